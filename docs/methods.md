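# Methods

This note documents the models implemented in `mechstrain`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions a user should know before trusting a number.

## Harmonic strain partitioning (JEDI)

Given a strained geometry and a relaxed reference that is a local minimum,
the strain energy is approximated harmonically,

ΔE ≈ ½ Δqᵀ H_q Δq,

in a redundant internal coordinate (RIC) space of bond lengths, bond angles
and dihedrals. The space is generated from a bond list: every pair of bonds
sharing an atom contributes a bending (shared atom as apex) and every
three-bond path i–j–k–l a torsion. Torsions whose central bendings come
within 5° of linearity are excluded because their Wilson rows diverge (the
threshold is configurable). No out-of-plane coordinates are used.

The Cartesian Hessian of the reference is transformed with the
Moore–Penrose pseudoinverse of the Wilson matrix B (rows ∂q_i/∂x, analytic
for all three coordinate types and validated against central finite
differences at 1e-5 Å steps): H_q = (B⁺)ᵀ H_x B⁺, symmetrized. Singular
values below 1e-8 of the largest are treated as exact null space — a
redundant set always has one. If B spans fewer than 3N−6 internal degrees
of freedom the transformation refuses to proceed ("incomplete coordinate
set") rather than silently losing strain. The gradient-correction term of
the coordinate transformation is omitted because the reference is an
optimized minimum; if a caller supplies a reference with gradient norm
above 1 kJ/mol/Å a warning is logged.

Per-coordinate strain uses the row-share attribution E_i = ½ Δq_i (H_qΔq)_i,
which splits each off-diagonal coupling evenly between its two coordinates.
This makes conservation exact (Σ E_i reproduces the quadratic form to
machine precision) at the cost of occasionally negative E_i; these are
reported as-is and only clamped at zero for visualization. When the total
is non-positive with a nonzero displacement the report is flagged and
percentages are suppressed. Torsion displacements are wrapped into (−π, π]
so a crossing of the ±180° seam contributes the short arc. When strain is
projected onto bonds for rendering, a bending donates half of its energy
to each leg and a torsion a third to each of its three consecutive bonds,
conserving the total.

With displacements drawn at random on the analytic cluster, the harmonic
total tracks the true energy difference to within about 2% for strains up
to 5 kJ/mol; the error grows roughly linearly with displacement amplitude
(Morse anharmonicity), which is why the trajectory pipeline pairs each
snapshot with its *own* relaxed reference instead of a global one.

## Force-modified surfaces and rupture forces (EFEI)

An external force F ≥ 0 between atoms a and b modifies the surface to
E′ = E − F·d(a,b) (nN converted at 60.2214 kJ/mol per nN·Å). Gradient and
Hessian of the tilt are analytic. Stationary points are force-balanced:
the internal restoring force along the pull axis equals F, which the tests
verify directly from the base-surface gradient at converged geometries.

The geometry optimizer is a damped BFGS with

* exact Cartesian freezing (frozen atoms are removed from the variable
  space, not restrained),
* a per-iteration step-norm cap (`max_step`, default 0.3 Å; 0.02 Å for the
  "tiny-step" relaxation that must find the *nearest* local minimum),
* convergence when the largest free-atom gradient component falls below
  0.05 kJ/mol/Å **and** the last step is below 1e-4 Å,
* an iteration cap (default 2000) reported through a `converged` flag
  rather than an exception — non-convergence is a physical signal consumed
  by rupture detection.

Angle constraints are enforced by stiff harmonic restraints
(k = 1e4 kJ/mol/rad²). The residual deviation equals the generalized
torque over k: about 0.6° at 1.5 nN on the cluster, shrinking linearly
with the load. Exact projection would remove this residual but is not
needed at the forces studied here.

A structure counts as ruptured when the optimization fails to converge
**or** the scissile bond exceeds 1.5× its zero-force length; both signals
are needed because a post-rupture minimum can exist. The rupture force is
bracketed by doubling from 0.5 nN and narrowed by bisection to the
requested resolution (0.01 nN default), restarting every trial from the
last intact geometry. These trials use the tiny 0.02 Å step cap: near the
critical force the barrier between the intact and ruptured valleys becomes
arbitrarily small, and ordinary 0.3 Å steps can hop it, misclassifying an
intact force as ruptured (on the Morse diatomic this error is ~0.3 nN).
With the tiny cap the bisection reproduces the analytic Morse maximum
D_e·β/2 = 2.242 nN to within one resolution step.

### What angle bending does — and does not — do on a separable surface

Constraining the terminal Fe–S–C bendings of the cluster to their
equilibrium values raises the rupture force (2.65 vs 2.44 nN at 0.01 nN
resolution): free bending lets the load path straighten, transmitting the
applied force more directly into the scissile bond, so bending facilitates
rupture. This reproduces the qualitative behavior reported for
quantum-chemical FeS₄ models.

The unconstrained cluster nevertheless ruptures *above* the isolated Morse
bond's 2.242 nN, and on this class of surface it must: in a force field
that is a sum of independent internal-coordinate terms, every non-bond
force on a chain atom acts perpendicular to its bond (angle-leg and
torsion-terminal gradients are orthogonal to the bond vector), so the
tension in the scissile bond is the applied force times a geometry factor
≤ 1 (measured 0.83–0.98 across angle stiffnesses of 30–400 kJ/mol/rad²).
Dropping *below* the isolated-bond threshold requires bend–stretch
coupling — an electronic-structure effect in which distorting an angle
weakens the adjacent bond — which a separable analytic potential cannot
express. Quantitative sub-threshold rupture forces therefore require an
external quantum-chemistry engine through the `Calculator` contract; the
analytic cluster is for validating the machinery, not for predicting
absolute rupture forces.

## The analytic cluster force field

The 21-atom pseudo-tetrahedral Fe(SCH₃)₄-like cluster uses

| interaction | form | default |
|---|---|---|
| Fe–S | Morse | D_e = 90 kJ/mol, β = 30 nm⁻¹, r₀ = 2.3 Å |
| S–C, C–H | ½k(r−r₀)² | k = 2000, 2900 kJ/mol/Å² |
| S–Fe–S, Fe–S–C | ½k(θ−θ₀)² | k = 100, 150 kJ/mol/rad² |
| S–C–H, H–C–H | ½k(θ−θ₀)² | k = 200, 150 kJ/mol/rad² |
| all torsions | k(1−cos 3(φ−φ₀)) | k = 1 kJ/mol |

The Morse parameters are the published anharmonic Fe–S values; the
remaining stiffnesses are generic organosulfur force-field magnitudes.
Equilibrium values default to the reference geometry the calculator is
built on, making that geometry an exact stationary point (gradient < 1e-6,
exactly six near-zero Hessian eigenvalues). Gradients are analytic and
vectorized; Hessians use central finite differences of the gradient
(1e-5 Å), adequate for a surface this smooth.

## Synthetic generators: what they emulate

**Pulling.** Steered-MD pulling is modeled as restrained quasi-static
minimization, not MD: per frame the pull-pair target separation advances
by speed·dt (defaults 0.2 nm/ns and 20 ps/frame, i.e. 0.04 Å/frame over
150 frames) and the geometry is re-minimized under a harmonic restraint of
7.0 kcal/mol/Å² — the standard pulling spring constant — starting from the
previous frame. Seeded Gaussian noise (default σ = 0.005 Å, uncorrelated
per coordinate) stands in for thermal jitter. The default pull pair is the
methyl carbon of arm 1 against Fe: single-arm loading makes the scissile
bond (Fe–S₁) unambiguous ground truth by construction, analogous to the
dominant load path through one cysteine arm; the symmetric two-carbon pull
of static rupture experiments is available through the protocol. The
ground-truth record keeps the noiseless geometries, scissile-bond lengths
(monotone non-decreasing) and per-term strain decompositions.

What this does **not** emulate: thermal ensembles and barrier recrossing,
solvent, the protein scaffold, and velocity-dependent (non-quasi-static)
effects. A passing round trip therefore shows the *analysis* recovers the
generator's ground truth, not that the generator reproduces real SMD.

**Hydrogen bonds.** Fixtures place the requested number of donor amide
hydrogens uniformly within [2.0, 2.9] Å of each sulfur acceptor and park
all others beyond 3.5 Å, using the nine rubredoxin donor residues (Lys6,
Ile7, Cys8, Gly9, Tyr10, Ile40, Cys41, Gly42, Ala43). The criterion is
distance-only (S–H ≤ 3.0 Å, boundary inclusive, no angle term), matching
how such contacts are counted for this system. Counts round-trip exactly
by construction.

## Trajectory pipeline

Per snapshot: (optional) quantum-region extraction — selected residues
plus any Fe, cut bonds hydrogen-capped along the original bond vector at
1.09 Å from carbon or 1.01 Å from nitrogen, link atoms flagged — then a
constrained optimization with the frozen-atom set (the "backbone" role;
N/Cα/C/O by convention for protein inputs, the pull pair for the cluster)
gives the strained geometry, and an unconstrained tiny-step relaxation
gives the relaxed reference. RIC topology is fixed from the first snapshot
so reports stay comparable across frames. Aggregates report the mean
strain percentage per coordinate with a 95% normal-approximation CI
(mean ± 1.96·SE over snapshots) and a time-resolved percentage table.
Frames whose scissile bond exceeds 1.5× its reference length are excluded
from aggregates as post-rupture. The frame stride is exposed rather than
hard-coded because the mapping from densely saved snapshots to analysis
frames is a sampling choice.

On the default seeded trajectory the scissile bond is the top-ranked bond
coordinate in 100% of post-midpoint intact frames, its percentage rises
monotonically toward rupture, and the >5% mean-percentage scaffold is
exactly the on-axis coordinate set {Fe–S₁, S₁–C₁, Fe–S₁–C₁}.

## Numerical conventions and edge cases

* Units: Å, ps, kJ/mol, nN; 1 nN·Å = 60.2214 kJ/mol, fixed in `constants`.
* Torsions follow the IUPAC sign convention (right-hand rule about j→k),
  values in (−π, π]; bendings in [0, π].
* Bond detection: d ≤ scale·(r_i + r_j) with Cordero-type covalent radii
  (high-spin value for Fe) and scale 1.3 by default; both overridable.
* PDB reading keeps the first alternate location and resolves elements
  from the element column with an atom-name fallback.
* Coincident atoms, near-linear bendings in Wilson rows, and empty bond
  lists raise immediately rather than propagating NaNs; non-finite
  energies abort the optimizer with `converged=False`.
* Strain percentages are reported relative to the (possibly small) total;
  the non-positive-total flag prevents division blow-ups.

## Problem sizes

The shipped tests and the acceptance script run entirely on the 21-atom
cluster and its diatomic fragment: 150-frame default pulling trajectories,
50-displacement harmonic-limit sweeps, 1000 random conservation draws, and
0.01 nN rupture bisections — about one minute end-to-end on a single CPU.
Larger systems are limited mainly by the dense pseudoinverse
(O(n_ric·(3N)²)) and the finite-difference Hessian (6N gradient calls);
both are per-snapshot costs that parallelize trivially across frames.

## Known limitations

* The harmonic strain model ignores anharmonic corrections and thermal
  averaging; it is a per-snapshot, zero-temperature analysis.
* The separable cluster force field cannot express bend–stretch coupling;
  see the rupture-force discussion above.
* No general hydrogen-bond perception: the NH⋯S criterion is deliberately
  the distance-only rule with an explicit donor list.
* The optional external-engine adapter is a contract, not a bundled DFT
  implementation; open-shell electronic effects (spin states, charge
  transfer) are entirely out of scope for the analytic surfaces.
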