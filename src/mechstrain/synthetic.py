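"""Synthetic inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here without a
molecular-dynamics engine or a quantum-chemistry code:

* an idealized pseudo-tetrahedral Fe(SCH₃)₄-like cluster (21 atoms) with an
  optional symmetry-broken variant,
* quasi-static pulling trajectories produced by re-minimizing the cluster
  under a stiff moving distance restraint (the generator's stand-in for a
  steered-MD pull), with controllable Gaussian positional noise,
* trajectory fixtures with amide-H/sulfur pairs at controlled distances for
  hydrogen-bond counting, using the rubredoxin donor residue names.

All randomness flows through one seeded generator per call; the seed is
recorded in the output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import KCAL_TO_KJ
from .geom_io import AtomicStructure, Trajectory
from .mechanochemistry import (
    Calculator,
    ForceFieldCalculator,
    HarmonicTerm,
    optimize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "build_toy_cluster",
    "PullProtocol",
    "PullGroundTruth",
    "generate_pull_trajectory",
    "generate_hbond_fixture",
    "DEFAULT_DONOR_RESIDUES",
]

_TETRAHEDRAL = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
) / np.sqrt(3.0)


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis`` by ``angle``."""
    return (v * np.cos(angle) + np.cross(axis, v) * np.sin(angle)
            + axis * np.dot(axis, v) * (1.0 - np.cos(angle)))


def _perp(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    p = ref - np.dot(ref, u) * u
    return p / np.linalg.norm(p)


def build_toy_cluster(fe_s_len: float = 2.3,
                      s_c_len: float = 1.82,
                      c_h_len: float = 1.09,
                      fe_s_c_angle_deg: float = 105.0,
                      methyl_torsions_deg: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
                      s_fe_s_jitter_deg: float = 0.0,
                      ) -> tuple[AtomicStructure, list[tuple[int, int]]]:
    """Deterministic 21-atom Fe(SCH₃)₄-like cluster plus its bond list.

    Atom order: Fe (0), S₁–S₄ (1–4), C₁–C₄ (5–8), then 3 H per methyl
    (9–20). By default the four Fe–S vectors point along ideal tetrahedral
    directions at 2.3 Å. ``methyl_torsions_deg`` staggers the methyl groups;
    ``s_fe_s_jitter_deg`` tilts the sulfur directions by a fixed pattern
    scaled to the given amplitude, producing unequal S–Fe–S angles (the
    symmetry-broken variant; the spread grows with the amplitude, roughly
    twice it at the extremes).
    """
    jitter = np.deg2rad(s_fe_s_jitter_deg)
    weights = (1.0, -0.6, 0.3, -0.1)  # fixed asymmetric tilt pattern
    dirs = []
    for k in range(4):
        u = _TETRAHEDRAL[k].copy()
        if jitter != 0.0:
            u = _rotate(u, _perp(u), jitter * weights[k])
        dirs.append(u / np.linalg.norm(u))

    theta_fsc = np.deg2rad(fe_s_c_angle_deg)
    alpha_sc = np.pi - theta_fsc       # S→C direction vs. outward Fe→S axis
    alpha_h = np.pi - np.deg2rad(109.47122)  # S–C–H tetrahedral

    coords = [np.zeros(3)]
    elements = ["Fe"]
    names = ["FE"]
    residues: list[tuple[int, str]] = [(1, "FE")]
    s_pos, c_pos = [], []
    for k, u in enumerate(dirs):
        s = fe_s_len * u
        p = _perp(u)
        d_sc = np.cos(alpha_sc) * u + np.sin(alpha_sc) * p
        c = s + s_c_len * d_sc
        s_pos.append(s)
        c_pos.append(c)
    coords += s_pos + c_pos
    elements += ["S"] * 4 + ["C"] * 4
    names += [f"S{k+1}" for k in range(4)] + [f"C{k+1}" for k in range(4)]
    residues += [(k + 2, "SCM") for k in range(4)]  # sulfurs
    residues += [(k + 2, "SCM") for k in range(4)]  # carbons

    for k in range(4):
        s, c = s_pos[k], c_pos[k]
        w = (c - s) / np.linalg.norm(c - s)
        a = _perp(w)
        b = np.cross(w, a)
        phi0 = np.deg2rad(methyl_torsions_deg[k])
        for m in range(3):
            phi = phi0 + m * 2.0 * np.pi / 3.0
            e = (np.cos(alpha_h) * w
                 + np.sin(alpha_h) * (np.cos(phi) * a + np.sin(phi) * b))
            coords.append(c + c_h_len * e)
            elements.append("H")
            names.append(f"H{k+1}{m+1}")
            residues.append((k + 2, "SCM"))

    structure = AtomicStructure(
        elements=tuple(elements),
        coords=np.array(coords),
        atom_names=tuple(names),
        residue_ids=tuple(residues),
    )
    bonds = sorted(
        [(0, 1 + k) for k in range(4)]
        + [(1 + k, 5 + k) for k in range(4)]
        + [(5 + k, 9 + 3 * k + m) for k in range(4) for m in range(3)]
    )
    return structure, bonds


# ---------------------------------------------------------------------------
# Quasi-static pulling trajectories
# ---------------------------------------------------------------------------

#: steered-MD-style pulling spring constant, 7.0 kcal/mol/Å² in kJ
DEFAULT_PULL_SPRING_K = 7.0 * KCAL_TO_KJ


@dataclass(frozen=True)
class PullProtocol:
    """Quasi-static pulling schedule.

    Defaults mirror the steered-MD settings the generator emulates: pulling
    speed 0.2 nm/ns with a 7.0 kcal/mol/Å² spring and one emitted frame per
    20 ps of simulated pulling. The default pull pair (methyl C of arm 1
    against Fe) loads a single Fe–S bond, making the scissile bond (Fe–S₁)
    unambiguous ground truth.
    """

    pull_pair: tuple[int, int] = (5, 0)
    speed_nm_ns: float = 0.2
    dt_ps: float = 20.0
    n_frames: int = 150
    noise_sigma: float = 0.005
    seed: int = 42
    spring_k: float = DEFAULT_PULL_SPRING_K
    scissile_bond: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if self.speed_nm_ns <= 0:
            raise ValueError("pull speed must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")

    @property
    def step_per_frame(self) -> float:
        """Restraint-target increment per frame, Å."""
        return self.speed_nm_ns * 0.01 * self.dt_ps


@dataclass
class PullGroundTruth:
    """What the generator actually did, for round-trip validation."""

    protocol: PullProtocol
    noiseless: list[AtomicStructure]
    scissile_lengths: np.ndarray
    total_strain: np.ndarray
    term_strains: list[dict[tuple[int, ...], float]] | None
    reference_energy: float


class _PullRestraintCalculator(Calculator):
    def __init__(self, base: Calculator, pair: tuple[int, int],
                 k: float, target: float):
        self.base = base
        self.term = HarmonicTerm(tuple(pair), k, target)

    def energy(self, coords: np.ndarray) -> float:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        return self.base.energy(coords) + self.term.value_and_deriv(
            self.term.q_and_grads(coords)[0])[0]

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        g = self.base.gradient(coords).reshape(-1, 3).copy()
        q, grads = self.term.q_and_grads(coords)
        dv = self.term.value_and_deriv(q)[1]
        for atom, gq in grads.items():
            g[atom] += dv * gq
        return g.reshape(-1)


def generate_pull_trajectory(calc: Calculator, start: AtomicStructure,
                             protocol: PullProtocol = PullProtocol(),
                             ) -> tuple[Trajectory, PullGroundTruth]:
    """Quasi-static pulling snapshots with a ground-truth record.

    Per frame the pull-pair target separation grows by speed·dt and the
    geometry is re-minimized under a stiff harmonic restraint to that target,
    starting from the previous minimized geometry; seeded Gaussian noise of
    ``noise_sigma`` Å is then added to the emitted coordinates. The
    ground-truth record keeps the noiseless geometries, the scissile-bond
    lengths, and per-frame strain computed directly on ``calc`` (per-term
    decomposition when the calculator exposes one).
    """
    rng = np.random.default_rng(protocol.seed)
    a, b = protocol.pull_pair
    d0 = start.distance(a, b)
    e_ref = calc.energy(start.coords)
    has_terms = isinstance(calc, ForceFieldCalculator)
    ref_terms = dict(calc.term_energies(start.coords)) if has_terms else None

    frames: list[AtomicStructure] = []
    noiseless: list[AtomicStructure] = []
    lengths, totals = [], []
    term_strains: list[dict[tuple[int, ...], float]] | None = [] if has_terms else None
    geom = start
    for f in range(1, protocol.n_frames + 1):
        target = d0 + f * protocol.step_per_frame
        restrained = _PullRestraintCalculator(calc, (a, b),
                                              protocol.spring_k, target)
        res = optimize(restrained, geom, max_step=0.3)
        if not res.converged:
            logger.warning("pull frame %d: re-minimization failed; "
                           "truncating trajectory", f)
            break
        geom = res.structure
        t = f * protocol.dt_ps
        clean = geom.with_coords(geom.coords, frame_time=t)
        noiseless.append(clean)
        lengths.append(clean.distance(*protocol.scissile_bond))
        totals.append(calc.energy(clean.coords) - e_ref)
        if has_terms:
            term_strains.append({
                idx: e - ref_terms[idx]
                for idx, e in calc.term_energies(clean.coords)
            })
        noisy = clean.coords + rng.normal(0.0, protocol.noise_sigma,
                                          size=clean.coords.shape)
        frame = clean.with_coords(noisy)
        frame.metadata.update(seed=protocol.seed, frame=f)
        frames.append(frame)

    if not frames:
        raise RuntimeError("pulling produced no frames")
    truth = PullGroundTruth(
        protocol=protocol,
        noiseless=noiseless,
        scissile_lengths=np.array(lengths),
        total_strain=np.array(totals),
        term_strains=term_strains,
        reference_energy=e_ref,
    )
    return Trajectory(frames), truth


# ---------------------------------------------------------------------------
# Hydrogen-bond fixtures
# ---------------------------------------------------------------------------

#: Backbone amide donors next to the FeS₄ unit in rubredoxin.
DEFAULT_DONOR_RESIDUES: tuple[tuple[int, str], ...] = (
    (6, "LYS"), (7, "ILE"), (8, "CYS"), (9, "GLY"), (10, "TYR"),
    (40, "ILE"), (41, "CYS"), (42, "GLY"), (43, "ALA"),
)

_ACCEPTOR_RESIDUES: tuple[tuple[int, str], ...] = ((5, "CYS"), (41, "CYS"))


def generate_hbond_fixture(layout: Sequence[Sequence[int]],
                           seed: int = 0,
                           dt_ps: float = 1.0) -> Trajectory:
    """Frames with exact per-acceptor hydrogen-bond counts.

    ``layout`` gives, per frame, the requested donor count near each of the
    two sulfur acceptors (atoms 0 and 1, residues Cys5 and Cys41). Selected
    donors place their amide H uniformly within [2.0, 2.9] Å of the acceptor;
    all other donors sit beyond 3.5 Å of every acceptor. The seed moves the
    donors around without changing any count.
    """
    rng = np.random.default_rng(seed)
    n_donors = len(DEFAULT_DONOR_RESIDUES)
    acceptor_pos = np.array([[0.0, 0.0, 0.0], [60.0, 0.0, 0.0]])

    elements = ["S", "S"] + ["N", "H"] * n_donors
    names = ["SG", "SG"]
    residues: list[tuple[int, str]] = list(_ACCEPTOR_RESIDUES)
    for rid in DEFAULT_DONOR_RESIDUES:
        names += ["N", "H"]
        residues += [rid, rid]

    frames = []
    for f, counts in enumerate(layout):
        counts = tuple(int(c) for c in counts)
        if len(counts) != 2:
            raise ValueError("layout entries must give counts for 2 acceptors")
        if sum(counts) > n_donors:
            raise ValueError(
                f"frame {f}: requested {sum(counts)} donors, "
                f"only {n_donors} available")
        order = rng.permutation(n_donors)
        assignment = {}
        pos = 0
        for acc, c in enumerate(counts):
            for d in order[pos:pos + c]:
                assignment[int(d)] = acc
            pos += c
        coords = np.zeros((2 + 2 * n_donors, 3))
        coords[:2] = acceptor_pos
        for d in range(n_donors):
            if d in assignment:
                acc = assignment[d]
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                dist = rng.uniform(2.0, 2.9)
                h = acceptor_pos[acc] + dist * u
                n_at = h + 1.0 * u
            else:
                h = np.array([30.0, 30.0 + 4.0 * d, 30.0])
                n_at = h + np.array([0.0, 0.0, 1.0])
            coords[2 + 2 * d] = n_at
            coords[3 + 2 * d] = h
        frame = AtomicStructure(
            elements=tuple(elements), coords=coords,
            atom_names=tuple(names), residue_ids=tuple(residues),
            frame_time=f * dt_ps,
        )
        frame.metadata.update(seed=seed, requested_counts=counts)
        frames.append(frame)
    return Trajectory(frames)
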