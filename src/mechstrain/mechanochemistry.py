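"""Force-modified potential-energy surfaces and rupture-force determination.

The EFEI scheme ("external force explicitly included") tilts a potential
energy surface by −F·d(a,b) for a pulled atom pair, so that stationary
points of the modified surface are force-balanced structures: the internal
restoring force along the pull axis cancels the applied force. Rupture
forces are found by a doubling/bisection search over the applied force at a
fixed resolution, restarting every trial from the previous intact geometry
(quasi-static continuation).

Analytic force-field calculators (Morse + harmonic + cosine terms) make the
whole machinery testable at desk scale; any external quantum-chemistry
engine can be plugged in through the same three-method Calculator contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .constants import NN_TO_KJ_PER_MOL_PER_ANGSTROM
from .geom_io import AtomicStructure
from .internal_coords import (
    _angle_grad,
    _bond_grad,
    _torsion_grad,
    angle_value,
    bond_value,
    build_ric,
    torsion_value,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Calculator",
    "ForceFieldCalculator",
    "MorseBondParams",
    "RuptureScanResult",
    "efei_wrap",
    "optimize",
    "OptimizationResult",
    "find_rupture_force",
    "toy_cluster_calculator",
    "morse_diatomic_calculator",
    "harmonic_diatomic_calculator",
    "restoring_force",
    "DEFAULT_TOY_PARAMS",
]


class Calculator:
    """Contract for a potential-energy surface.

    ``energy`` returns kJ/mol, ``gradient`` a flat 3N vector in kJ/mol/Å,
    ``hessian`` a 3N×3N matrix in kJ/mol/Å² (default: central finite
    difference of the gradient, symmetrized).
    """

    #: finite-difference step (Å) for the default Hessian
    fd_step: float = 1e-5

    def energy(self, coords: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def hessian(self, coords: np.ndarray) -> np.ndarray:
        x = np.asarray(coords, dtype=float).reshape(-1)
        n = x.size
        h = np.empty((n, n))
        step = self.fd_step
        for k in range(n):
            xp, xm = x.copy(), x.copy()
            xp[k] += step
            xm[k] -= step
            h[k] = (self.gradient(xp.reshape(-1, 3))
                    - self.gradient(xm.reshape(-1, 3))) / (2.0 * step)
        return 0.5 * (h + h.T)


# ---------------------------------------------------------------------------
# Analytic force-field terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorseBondParams:
    """Morse bond V(r) = D_e (1 − e^{−β(r−r₀)})².

    ``de`` in kJ/mol, ``beta_nm`` in nm⁻¹ (the unit the parameters are
    usually quoted in), ``r0`` in Å. The maximum restoring force is
    D_e·β/2, reached at r₀ + ln2/β.
    """

    de: float
    beta_nm: float
    r0: float

    def __post_init__(self) -> None:
        if not (self.de > 0 and self.beta_nm > 0 and self.r0 > 0):
            raise ValueError("Morse parameters must all be positive")

    @property
    def beta_angstrom(self) -> float:
        return self.beta_nm / 10.0

    @property
    def max_force_kj_mol_angstrom(self) -> float:
        return self.de * self.beta_angstrom / 2.0

    @property
    def max_force_nn(self) -> float:
        return self.max_force_kj_mol_angstrom / NN_TO_KJ_PER_MOL_PER_ANGSTROM


@dataclass(frozen=True)
class _Term:
    indices: tuple[int, ...]

    def value_and_deriv(self, q: float) -> tuple[float, float]:
        raise NotImplementedError

    def q_and_grads(self, coords: np.ndarray):
        idx = self.indices
        if len(idx) == 2:
            return bond_value(coords, *idx), _bond_grad(coords, *idx)
        if len(idx) == 3:
            return angle_value(coords, *idx), _angle_grad(coords, *idx)
        return torsion_value(coords, *idx), _torsion_grad(coords, *idx)


@dataclass(frozen=True)
class MorseTerm(_Term):
    params: MorseBondParams

    def value_and_deriv(self, q: float) -> tuple[float, float]:
        p = self.params
        b = p.beta_angstrom
        ex = np.exp(-b * (q - p.r0))
        return p.de * (1.0 - ex) ** 2, 2.0 * p.de * b * ex * (1.0 - ex)


@dataclass(frozen=True)
class HarmonicTerm(_Term):
    """½ k (q − q₀)²; covers bonds (k in kJ/mol/Å²), bendings and angle
    restraints (k in kJ/mol/rad²)."""

    k: float
    q0: float

    def value_and_deriv(self, q: float) -> tuple[float, float]:
        d = q - self.q0
        if len(self.indices) == 4:  # periodic coordinate
            d = (d + np.pi) % (2.0 * np.pi) - np.pi
        return 0.5 * self.k * d * d, self.k * d


@dataclass(frozen=True)
class CosineTorsionTerm(_Term):
    """k (1 − cos n(φ − φ₀)); minimum at φ₀ and its n-fold images."""

    k: float
    n: int
    phi0: float

    def value_and_deriv(self, q: float) -> tuple[float, float]:
        arg = self.n * (q - self.phi0)
        return self.k * (1.0 - np.cos(arg)), self.k * self.n * np.sin(arg)


# --- vectorized geometry kernels (arrays of bonds / bendings / torsions) ---

def _bond_geom(c: np.ndarray, idx: np.ndarray):
    d = c[idx[:, 1]] - c[idx[:, 0]]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-8):
        raise ValueError("coincident bonded atoms")
    u = d / r[:, None]
    return r, u


def _angle_geom(c: np.ndarray, idx: np.ndarray):
    u = c[idx[:, 0]] - c[idx[:, 1]]
    v = c[idx[:, 2]] - c[idx[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    cos = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    sin = np.sqrt(np.maximum(1.0 - cos * cos, 1e-16))
    theta = np.arccos(cos)
    gi = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
    gk = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
    return theta, gi, gk, -(gi + gk)


def _torsion_geom(c: np.ndarray, idx: np.ndarray):
    b1 = c[idx[:, 1]] - c[idx[:, 0]]
    b2 = c[idx[:, 2]] - c[idx[:, 1]]
    b3 = c[idx[:, 3]] - c[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    sq1 = np.einsum("ij,ij->i", n1, n1)
    sq2 = np.einsum("ij,ij->i", n2, n2)
    phi = np.arctan2(
        np.einsum("ij,ij->i", np.cross(n1, n2), b2) / nb2,
        np.einsum("ij,ij->i", n1, n2),
    )
    gi = -(nb2 / sq1)[:, None] * n1
    gl = (nb2 / sq2)[:, None] * n2
    c12 = np.einsum("ij,ij->i", b1, b2) / (nb2 * nb2)
    c32 = np.einsum("ij,ij->i", b3, b2) / (nb2 * nb2)
    gj = -(1.0 + c12)[:, None] * gi + c32[:, None] * gl
    gk = c12[:, None] * gi - (1.0 + c32)[:, None] * gl
    return phi, gi, gj, gk, gl


class ForceFieldCalculator(Calculator):
    """Sum of analytic internal-coordinate terms with analytic gradient.

    Terms are compiled into per-class index/parameter arrays at construction
    so that energies and gradients evaluate through vectorized kernels.
    """

    def __init__(self, n_atoms: int, terms: Sequence[_Term]):
        self.n_atoms = n_atoms
        self.terms = list(terms)
        morse, harm2, harm3, harm4, cos4 = [], [], [], [], []
        for t in self.terms:
            if isinstance(t, MorseTerm):
                morse.append(t)
            elif isinstance(t, CosineTorsionTerm):
                cos4.append(t)
            elif isinstance(t, HarmonicTerm):
                (harm2, harm3, harm4)[len(t.indices) - 2].append(t)
            else:
                raise TypeError(f"unknown term type {type(t).__name__}")
        self._morse_idx = np.array([t.indices for t in morse], int).reshape(-1, 2)
        self._morse_p = np.array(
            [(t.params.de, t.params.beta_angstrom, t.params.r0) for t in morse]
        ).reshape(-1, 3)
        self._h2_idx = np.array([t.indices for t in harm2], int).reshape(-1, 2)
        self._h2_p = np.array([(t.k, t.q0) for t in harm2]).reshape(-1, 2)
        self._h3_idx = np.array([t.indices for t in harm3], int).reshape(-1, 3)
        self._h3_p = np.array([(t.k, t.q0) for t in harm3]).reshape(-1, 2)
        self._h4_idx = np.array([t.indices for t in harm4], int).reshape(-1, 4)
        self._h4_p = np.array([(t.k, t.q0) for t in harm4]).reshape(-1, 2)
        self._c4_idx = np.array([t.indices for t in cos4], int).reshape(-1, 4)
        self._c4_p = np.array([(t.k, t.n, t.phi0) for t in cos4]).reshape(-1, 3)

    def _group_energies(self, c: np.ndarray) -> list[np.ndarray]:
        out = []
        if len(self._morse_idx):
            r, _ = _bond_geom(c, self._morse_idx)
            de, beta, r0 = self._morse_p.T
            ex = np.exp(-beta * (r - r0))
            out.append(de * (1.0 - ex) ** 2)
        else:
            out.append(np.empty(0))
        if len(self._h2_idx):
            r, _ = _bond_geom(c, self._h2_idx)
            k, q0 = self._h2_p.T
            out.append(0.5 * k * (r - q0) ** 2)
        else:
            out.append(np.empty(0))
        if len(self._h3_idx):
            theta = _angle_geom(c, self._h3_idx)[0]
            k, q0 = self._h3_p.T
            out.append(0.5 * k * (theta - q0) ** 2)
        else:
            out.append(np.empty(0))
        if len(self._h4_idx):
            phi = _torsion_geom(c, self._h4_idx)[0]
            k, q0 = self._h4_p.T
            d = (phi - q0 + np.pi) % (2.0 * np.pi) - np.pi
            out.append(0.5 * k * d * d)
        else:
            out.append(np.empty(0))
        if len(self._c4_idx):
            phi = _torsion_geom(c, self._c4_idx)[0]
            k, n, phi0 = self._c4_p.T
            out.append(k * (1.0 - np.cos(n * (phi - phi0))))
        else:
            out.append(np.empty(0))
        return out

    def energy(self, coords: np.ndarray) -> float:
        c = np.asarray(coords, dtype=float).reshape(-1, 3)
        return float(sum(e.sum() for e in self._group_energies(c)))

    def term_energies(self, coords: np.ndarray) -> list[tuple[tuple[int, ...], float]]:
        """Per-interaction energies — the generator's ground-truth hook."""
        c = np.asarray(coords, dtype=float).reshape(-1, 3)
        groups = self._group_energies(c)
        idx_groups = (self._morse_idx, self._h2_idx, self._h3_idx,
                      self._h4_idx, self._c4_idx)
        out = []
        for idx, en in zip(idx_groups, groups):
            out.extend((tuple(int(a) for a in row), float(e))
                       for row, e in zip(idx, en))
        return out

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        c = np.asarray(coords, dtype=float).reshape(-1, 3)
        g = np.zeros((self.n_atoms, 3))

        def acc(idx_col, contrib):
            np.add.at(g, idx_col, contrib)

        if len(self._morse_idx):
            r, u = _bond_geom(c, self._morse_idx)
            de, beta, r0 = self._morse_p.T
            ex = np.exp(-beta * (r - r0))
            dv = (2.0 * de * beta * ex * (1.0 - ex))[:, None]
            acc(self._morse_idx[:, 0], -dv * u)
            acc(self._morse_idx[:, 1], dv * u)
        if len(self._h2_idx):
            r, u = _bond_geom(c, self._h2_idx)
            k, q0 = self._h2_p.T
            dv = (k * (r - q0))[:, None]
            acc(self._h2_idx[:, 0], -dv * u)
            acc(self._h2_idx[:, 1], dv * u)
        if len(self._h3_idx):
            theta, gi, gk, gj = _angle_geom(c, self._h3_idx)
            k, q0 = self._h3_p.T
            dv = (k * (theta - q0))[:, None]
            acc(self._h3_idx[:, 0], dv * gi)
            acc(self._h3_idx[:, 1], dv * gj)
            acc(self._h3_idx[:, 2], dv * gk)
        if len(self._h4_idx):
            phi, gi, gj, gk, gl = _torsion_geom(c, self._h4_idx)
            k, q0 = self._h4_p.T
            d = (phi - q0 + np.pi) % (2.0 * np.pi) - np.pi
            dv = (k * d)[:, None]
            for col, gg in enumerate((gi, gj, gk, gl)):
                acc(self._h4_idx[:, col], dv * gg)
        if len(self._c4_idx):
            phi, gi, gj, gk, gl = _torsion_geom(c, self._c4_idx)
            k, n, phi0 = self._c4_p.T
            dv = (k * n * np.sin(n * (phi - phi0)))[:, None]
            for col, gg in enumerate((gi, gj, gk, gl)):
                acc(self._c4_idx[:, col], dv * gg)
        return g.reshape(-1)


# ---------------------------------------------------------------------------
# Simple diatomics (worked examples and closed-form oracles)
# ---------------------------------------------------------------------------

def morse_diatomic_calculator(
        params: MorseBondParams = MorseBondParams(90.0, 30.0, 2.3),
) -> ForceFieldCalculator:
    """Two atoms bound by a single Morse potential (defaults: the Fe–S
    parameters D_e = 90 kJ/mol, β = 30 nm⁻¹, r₀ = 2.3 Å)."""
    return ForceFieldCalculator(2, [MorseTerm((0, 1), params)])


def harmonic_diatomic_calculator(k: float = 2000.0,
                                 r0: float = 1.0) -> ForceFieldCalculator:
    return ForceFieldCalculator(2, [HarmonicTerm((0, 1), k, r0)])


# ---------------------------------------------------------------------------
# EFEI wrapper
# ---------------------------------------------------------------------------

class _EFEICalculator(Calculator):
    def __init__(self, base: Calculator, pull_pair: tuple[int, int],
                 force_nn: float):
        self.base = base
        self.pull_pair = pull_pair
        self.force_nn = force_nn
        self._f = force_nn * NN_TO_KJ_PER_MOL_PER_ANGSTROM  # kJ/mol/Å

    def _axis(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        a, b = self.pull_pair
        d = coords[b] - coords[a]
        r = float(np.linalg.norm(d))
        if r < 1e-8:
            raise ValueError(f"pulled atoms {a}, {b} are coincident")
        return r, d / r

    def energy(self, coords: np.ndarray) -> float:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        r, _ = self._axis(coords)
        return self.base.energy(coords) - self._f * r

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        _, u = self._axis(coords)
        g = self.base.gradient(coords).reshape(-1, 3).copy()
        a, b = self.pull_pair
        g[a] += self._f * u
        g[b] -= self._f * u
        return g.reshape(-1)

    def hessian(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        r, u = self._axis(coords)
        h = np.array(self.base.hessian(coords), dtype=float)
        block = (np.eye(3) - np.outer(u, u)) / r  # ∂²d/∂x², aa block
        a, b = self.pull_pair
        for (p, q, sign) in ((a, a, 1.0), (b, b, 1.0), (a, b, -1.0), (b, a, -1.0)):
            h[3 * p:3 * p + 3, 3 * q:3 * q + 3] -= self._f * sign * block
        return h


def efei_wrap(base: Calculator, pull_pair: tuple[int, int],
              force: float) -> Calculator:
    """Tilt ``base`` by −F·d(a,b): the EFEI force-modified surface.

    ``force`` is in nN and must be ≥ 0; F = 0 returns a wrapper that is
    numerically identical to the base surface.
    """
    a, b = pull_pair
    if a == b:
        raise ValueError("pull pair must be two distinct atoms")
    if force < 0:
        raise ValueError("force must be non-negative")
    return _EFEICalculator(base, (a, b), force)


def restoring_force(base: Calculator, coords: np.ndarray,
                    pull_pair: tuple[int, int]) -> float:
    """Internal restoring force (nN) along the pull axis.

    At a converged EFEI geometry this equals the applied force (the applied
    and internal forces cancel at stationary points).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    a, b = pull_pair
    d = coords[b] - coords[a]
    u = d / np.linalg.norm(d)
    g = base.gradient(coords).reshape(-1, 3)
    f_int = 0.5 * float(np.dot(g[b] - g[a], u))
    return f_int / NN_TO_KJ_PER_MOL_PER_ANGSTROM


# ---------------------------------------------------------------------------
# Constrained geometry optimization
# ---------------------------------------------------------------------------

@dataclass
class OptimizationResult:
    structure: AtomicStructure
    converged: bool
    n_iterations: int
    energy: float
    max_gradient: float
    aborted: bool = False


class _RestrainedCalculator(Calculator):
    """Base surface plus stiff harmonic angle restraints."""

    def __init__(self, base: Calculator,
                 angle_constraints: Sequence[tuple[int, int, int, float]],
                 k_restraint: float):
        self.base = base
        self.terms = [HarmonicTerm((i, j, k), k_restraint, float(target))
                      for (i, j, k, target) in angle_constraints]

    def energy(self, coords: np.ndarray) -> float:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        e = self.base.energy(coords)
        for t in self.terms:
            e += t.value_and_deriv(t.q_and_grads(coords)[0])[0]
        return float(e)

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        g = self.base.gradient(coords).reshape(-1, 3).copy()
        for t in self.terms:
            q, grads = t.q_and_grads(coords)
            dv = t.value_and_deriv(q)[1]
            for atom, gq in grads.items():
                g[atom] += dv * gq
        return g.reshape(-1)


#: restraint stiffness for angle constraints, kJ/mol/rad²
ANGLE_RESTRAINT_K = 1.0e4

#: convergence thresholds of the optimizer
GRAD_TOL = 0.05      # kJ/mol/Å, max component over free atoms
STEP_TOL = 1e-4      # Å, displacement norm


def optimize(calc: Calculator, start: AtomicStructure,
             frozen_atoms: Sequence[int] = (),
             max_step: float = 0.3,
             angle_constraints: Sequence[tuple[int, int, int, float]] | None = None,
             grad_tol: float = GRAD_TOL,
             step_tol: float = STEP_TOL,
             max_iterations: int = 2000,
             abort_check: Callable[[np.ndarray], bool] | None = None,
             ) -> OptimizationResult:
    """Local minimization with exactly frozen Cartesian atoms.

    Damped BFGS with the per-iteration displacement norm capped at
    ``max_step`` (a small cap implements the tiny-step relaxation that finds
    the *nearest* local minimum). Convergence requires both the max gradient
    component over free atoms below ``grad_tol`` and the last step norm below
    ``step_tol``. Exceeding ``max_iterations`` is reported through the
    ``converged`` flag, not an exception — rupture detection consumes it.
    ``angle_constraints`` are (i, j, k, target_radians) tuples enforced by a
    stiff harmonic restraint. ``abort_check`` may stop the optimization early
    (result flagged ``aborted`` and not converged).
    """
    if max_step <= 0:
        raise ValueError("max_step must be positive")
    n = start.n_atoms
    frozen = sorted(set(int(i) for i in frozen_atoms))
    if any(not 0 <= i < n for i in frozen):
        raise ValueError("frozen atom index out of range")
    if angle_constraints:
        calc = _RestrainedCalculator(calc, angle_constraints, ANGLE_RESTRAINT_K)

    free_mask = np.ones(3 * n, dtype=bool)
    for i in frozen:
        free_mask[3 * i:3 * i + 3] = False
    x = np.array(start.coords, dtype=float).reshape(-1)
    nfree = int(free_mask.sum())

    def grad_free(xv: np.ndarray) -> np.ndarray:
        return calc.gradient(xv.reshape(-1, 3))[free_mask]

    def max_g(g: np.ndarray) -> float:
        return float(np.abs(g).max()) if g.size else 0.0

    g = grad_free(x)
    if max_g(g) < grad_tol:
        return OptimizationResult(start.with_coords(x.reshape(-1, 3)), True, 0,
                                  calc.energy(x.reshape(-1, 3)), max_g(g))

    h_inv = np.eye(nfree)
    scaled = False
    e = calc.energy(x.reshape(-1, 3))
    converged = False
    aborted = False
    it = 0
    for it in range(1, max_iterations + 1):
        p = -h_inv @ g
        pn = float(np.linalg.norm(p))
        if pn > max_step:
            p *= max_step / pn
        # backtracking line search (Armijo); keep the best energy seen
        slope = float(np.dot(g, p))
        alpha, best_alpha, best_e = 1.0, None, np.inf
        for _ in range(12):
            x_try = x.copy()
            x_try[free_mask] += alpha * p
            e_try = calc.energy(x_try.reshape(-1, 3))
            if e_try < best_e:
                best_e, best_alpha = e_try, alpha
            if e_try <= e + 1e-4 * alpha * slope:
                break
            alpha *= 0.5
        if best_alpha is None:  # energy not finite anywhere along p
            break
        if best_e >= e:  # no descent along p: reset curvature model
            h_inv = np.eye(nfree)
            scaled = False
            best_alpha = min(1.0, 1e-2 / max(pn, 1e-12))
            best_e = None
        s = best_alpha * p
        x_new = x.copy()
        x_new[free_mask] += s
        g_new = grad_free(x_new)
        e = best_e if best_e is not None else calc.energy(x_new.reshape(-1, 3))
        step_norm = float(np.linalg.norm(s))

        y = g_new - g
        sy = float(np.dot(s, y))
        if sy > 1e-12:
            if not scaled:
                h_inv *= sy / float(np.dot(y, y))
                scaled = True
            rho = 1.0 / sy
            v = np.eye(nfree) - rho * np.outer(s, y)
            h_inv = v @ h_inv @ v.T + rho * np.outer(s, s)
        x, g = x_new, g_new

        if abort_check is not None and abort_check(x.reshape(-1, 3)):
            aborted = True
            break
        if max_g(g) < grad_tol and step_norm < step_tol:
            converged = True
            break

    result_structure = start.with_coords(x.reshape(-1, 3))
    return OptimizationResult(result_structure, converged, it,
                              calc.energy(x.reshape(-1, 3)), max_g(g),
                              aborted=aborted)


# ---------------------------------------------------------------------------
# Rupture-force search
# ---------------------------------------------------------------------------

@dataclass
class ForceTrial:
    force_nn: float
    converged: bool
    ruptured: bool
    scissile_length: float


@dataclass
class RuptureScanResult:
    """Outcome of the iterative rupture-force determination."""

    bracket_low: float
    bracket_high: float
    rupture_force: float
    resolution: float
    trials: list[ForceTrial] = field(default_factory=list)
    reference_length: float = float("nan")

    def __post_init__(self) -> None:
        if self.bracket_high - self.bracket_low > self.resolution + 1e-12:
            raise ValueError("bracket wider than resolution at convergence")
        if not (self.bracket_low < self.rupture_force <= self.bracket_high):
            raise ValueError("rupture force outside final bracket")


class RuptureError(RuntimeError):
    pass


def find_rupture_force(base: Calculator, start: AtomicStructure,
                       pull_pair: tuple[int, int],
                       scissile_bond: tuple[int, int],
                       resolution: float = 0.01,
                       rupture_length_factor: float = 1.5,
                       force_cap: float = 10.0,
                       bracket_start: float = 0.5,
                       angle_constraints: Sequence[tuple[int, int, int, float]] | None = None,
                       max_step: float = 0.02,
                       max_iterations: int = 2000,
                       ) -> RuptureScanResult:
    """Smallest force (nN) at which no intact force-balanced structure exists.

    A geometry is "ruptured" when the EFEI optimization fails to converge or
    the scissile bond exceeds ``rupture_length_factor`` times its zero-force
    length (both signals are needed: a post-rupture minimum can exist). A
    doubling search from ``bracket_start`` nN finds an upper bracket, then
    bisection narrows it to ``resolution``; the reported rupture force is the
    bracket top. Every trial restarts from the last intact geometry, with a
    tiny step cap so the optimizer stays in the intact basin whenever one
    exists (near the critical force the barrier separating it from the
    ruptured valley becomes arbitrarily small).
    """
    i, j = scissile_bond
    res0 = optimize(base, start, max_step=max_step,
                    angle_constraints=angle_constraints,
                    max_iterations=max_iterations)
    if not res0.converged:
        raise RuptureError("zero-force optimization did not converge")
    ref_len = res0.structure.distance(i, j)
    limit = rupture_length_factor * ref_len
    trials: list[ForceTrial] = []

    def trial(force: float, geom: AtomicStructure) -> tuple[bool, OptimizationResult]:
        calc = efei_wrap(base, pull_pair, force)

        def broken(c: np.ndarray) -> bool:
            return float(np.linalg.norm(c[j] - c[i])) > limit

        res = optimize(calc, geom, max_step=max_step,
                       angle_constraints=angle_constraints,
                       max_iterations=max_iterations, abort_check=broken)
        length = res.structure.distance(i, j)
        ruptured = (not res.converged) or length > limit
        trials.append(ForceTrial(force, res.converged, ruptured, length))
        return ruptured, res

    low, geom = 0.0, res0.structure
    force = bracket_start
    high = None
    while force <= force_cap:
        ruptured, res = trial(force, geom)
        if ruptured:
            high = force
            break
        low, geom = force, res.structure
        force *= 2.0
    if high is None:
        raise RuptureError(f"no rupture in range (force cap {force_cap} nN)")

    while high - low > resolution:
        mid = 0.5 * (low + high)
        ruptured, res = trial(mid, geom)
        if ruptured:
            high = mid
        else:
            low, geom = mid, res.structure

    return RuptureScanResult(bracket_low=low, bracket_high=high,
                             rupture_force=high, resolution=resolution,
                             trials=trials, reference_length=ref_len)


# ---------------------------------------------------------------------------
# The pseudo-tetrahedral Fe(SCH₃)₄ force field
# ---------------------------------------------------------------------------

#: Default parameter table for the 21-atom cluster. Morse Fe–S uses the
#: published anharmonic parameters; the remaining stiffnesses are generic
#: force-field magnitudes (kJ/mol/Å² for stretches with the ½k convention,
#: kJ/mol/rad² for bendings, kJ/mol with 3-fold periodicity for torsions).
#: Equilibrium values default to the reference geometry the calculator is
#: built on, so that geometry is an exact minimum.
DEFAULT_TOY_PARAMS: dict = {
    ("morse", ("Fe", "S")): MorseBondParams(de=90.0, beta_nm=30.0, r0=2.3),
    ("bond", ("C", "S")): {"k": 2000.0},
    ("bond", ("C", "H")): {"k": 2900.0},
    # key: (end1, end2, apex) with the end elements sorted
    ("angle", ("S", "S", "Fe")): {"k": 100.0},
    ("angle", ("C", "Fe", "S")): {"k": 150.0},
    ("angle", ("H", "S", "C")): {"k": 200.0},
    ("angle", ("H", "H", "C")): {"k": 150.0},
    ("torsion", "default"): {"k": 1.0, "n": 3},
}


def toy_cluster_calculator(structure: AtomicStructure | None = None,
                           bonds: Sequence[tuple[int, int]] | None = None,
                           params: Mapping | None = None
                           ) -> ForceFieldCalculator:
    """Analytic force field for the Fe(SCH₃)₄-like cluster.

    Fe–S bonds are Morse (published parameters by default); S–C and C–H are
    harmonic stretches; all bendings are harmonic; all torsions are 3-fold
    cosines. Equilibrium values are taken from the reference ``structure``
    unless overridden in ``params``, so the reference is a stationary point.
    With no arguments, the ideal tetrahedral cluster is built and used.
    """
    if structure is None or bonds is None:
        from .synthetic import build_toy_cluster
        structure, bonds = build_toy_cluster()
    table = dict(DEFAULT_TOY_PARAMS)
    if params:
        table.update(params)
    table = {k: v for k, v in table.items() if v is not None}  # None = remove
    coords = structure.coords
    elems = structure.elements
    ric = build_ric(structure, list(bonds))
    terms: list[_Term] = []
    for (i, j) in ric.bonds:
        pair = tuple(sorted((elems[i], elems[j])))
        if ("morse", pair) in table:
            terms.append(MorseTerm((i, j), table[("morse", pair)]))
        elif ("bond", pair) in table:
            p = table[("bond", pair)]
            r0 = p.get("r0", bond_value(coords, i, j))
            terms.append(HarmonicTerm((i, j), p["k"], r0))
        else:
            raise KeyError(f"no bond parameters for {pair[0]}-{pair[1]}")
    for (i, j, k) in ric.angles:
        key = ("angle", (*sorted((elems[i], elems[k])), elems[j]))
        if key not in table:
            raise KeyError(
                f"no angle parameters for {elems[i]}-{elems[j]}-{elems[k]}")
        p = table[key]
        theta0 = p.get("theta0", angle_value(coords, i, j, k))
        terms.append(HarmonicTerm((i, j, k), p["k"], theta0))
    tor = table.get(("torsion", "default"))
    if tor is None:
        raise KeyError("no default torsion parameters")
    for (i, j, k, l) in ric.torsions:
        phi0 = torsion_value(coords, i, j, k, l)
        terms.append(CosineTorsionTerm((i, j, k, l), tor["k"], tor["n"], phi0))
    return ForceFieldCalculator(structure.n_atoms, terms)
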