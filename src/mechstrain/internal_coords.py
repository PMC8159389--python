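"""Redundant internal coordinates (RIC): bonds, bendings, torsions.

Provides the coordinate value functions and their analytic Cartesian first
derivatives (the rows of the Wilson B matrix), the automatic construction of
the full redundant set from a bond list, and displacement vectors between two
geometries with proper torsion wrapping.

Conventions: bond lengths in Å, angles/torsions in radians; torsions follow
the IUPAC sign convention (right-hand rule about the j→k axis, values in
(−π, π]); angle values lie in [0, π].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geom_io import AtomicStructure

__all__ = [
    "InternalCoordinateSet",
    "build_ric",
    "ric_values",
    "delta_q",
    "wilson_b",
    "bond_value",
    "angle_value",
    "torsion_value",
]

_DEGENERATE_TOL = 1e-8


def _vec(coords: np.ndarray, a: int, b: int) -> np.ndarray:
    return coords[b] - coords[a]


def bond_value(coords: np.ndarray, i: int, j: int) -> float:
    r = float(np.linalg.norm(_vec(coords, i, j)))
    if r < _DEGENERATE_TOL:
        raise ValueError(f"coincident atoms {i}, {j}")
    return r


def angle_value(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i–j–k (apex j), in [0, π]."""
    u = _vec(coords, j, i)
    v = _vec(coords, j, k)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _DEGENERATE_TOL or nv < _DEGENERATE_TOL:
        raise ValueError(f"degenerate angle ({i},{j},{k}): coincident atoms")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(cosang))


def torsion_value(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Dihedral i–j–k–l about the j–k bond, IUPAC sign, in (−π, π]."""
    b1 = _vec(coords, i, j)
    b2 = _vec(coords, j, k)
    b3 = _vec(coords, k, l)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < _DEGENERATE_TOL:
        raise ValueError(f"degenerate torsion ({i},{j},{k},{l}): coincident axis")
    phi = float(np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2)))
    return phi if phi > -np.pi else np.pi


def _bond_grad(coords: np.ndarray, i: int, j: int) -> dict[int, np.ndarray]:
    d = _vec(coords, i, j)
    r = np.linalg.norm(d)
    if r < _DEGENERATE_TOL:
        raise ValueError(f"coincident atoms {i}, {j}")
    u = d / r
    return {i: -u, j: u}


def _angle_grad(coords: np.ndarray, i: int, j: int, k: int
                ) -> dict[int, np.ndarray]:
    u = _vec(coords, j, i)
    v = _vec(coords, j, k)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _DEGENERATE_TOL or nv < _DEGENERATE_TOL:
        raise ValueError(f"degenerate angle ({i},{j},{k})")
    uh, vh = u / nu, v / nv
    cosang = np.clip(np.dot(uh, vh), -1.0, 1.0)
    sinang = np.sqrt(max(1.0 - cosang * cosang, 0.0))
    if sinang < _DEGENERATE_TOL:
        raise ValueError(f"angle ({i},{j},{k}) is linear; derivative undefined")
    gi = (cosang * uh - vh) / (nu * sinang)
    gk = (cosang * vh - uh) / (nv * sinang)
    return {i: gi, k: gk, j: -(gi + gk)}


def _torsion_grad(coords: np.ndarray, i: int, j: int, k: int, l: int
                  ) -> dict[int, np.ndarray]:
    b1 = _vec(coords, i, j)
    b2 = _vec(coords, j, k)
    b3 = _vec(coords, k, l)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    sq1, sq2 = np.dot(n1, n1), np.dot(n2, n2)
    if nb2 < _DEGENERATE_TOL or sq1 < _DEGENERATE_TOL**2 or sq2 < _DEGENERATE_TOL**2:
        raise ValueError(f"degenerate torsion ({i},{j},{k},{l})")
    gi = -nb2 / sq1 * n1
    gl = nb2 / sq2 * n2
    c12 = np.dot(b1, b2) / (nb2 * nb2)
    c32 = np.dot(b3, b2) / (nb2 * nb2)
    gj = -(1.0 + c12) * gi + c32 * gl
    gk = c12 * gi - (1.0 + c32) * gl
    return {i: gi, j: gj, k: gk, l: gl}


@dataclass
class InternalCoordinateSet:
    """Typed redundant internal coordinates with their current values.

    ``values`` concatenates bond, angle and torsion values in that order,
    matching the lexicographically sorted coordinate lists.
    """

    bonds: tuple[tuple[int, int], ...]
    angles: tuple[tuple[int, int, int], ...]
    torsions: tuple[tuple[int, int, int, int], ...]
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bonds = tuple(tuple(b) for b in self.bonds)
        self.angles = tuple(tuple(a) for a in self.angles)
        self.torsions = tuple(tuple(t) for t in self.torsions)
        for tup in (*self.bonds, *self.angles, *self.torsions):
            if len(set(tup)) != len(tup):
                raise ValueError(f"repeated atom index in coordinate {tup}")
            if any(i < 0 for i in tup):
                raise ValueError(f"negative atom index in coordinate {tup}")
        if self.values is None:
            self.values = np.full(self.n, np.nan)
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.shape != (self.n,):
                raise ValueError("values length does not match coordinate count")

    @property
    def n(self) -> int:
        return len(self.bonds) + len(self.angles) + len(self.torsions)

    @property
    def definitions(self) -> tuple[tuple[int, ...], ...]:
        return (*self.bonds, *self.angles, *self.torsions)

    @property
    def kinds(self) -> tuple[str, ...]:
        return (("bond",) * len(self.bonds) + ("angle",) * len(self.angles)
                + ("torsion",) * len(self.torsions))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(
            f"{kind}({'-'.join(str(i) for i in tup)})"
            for kind, tup in zip(self.kinds, self.definitions)
        )

    def same_definitions(self, other: "InternalCoordinateSet") -> bool:
        return (self.bonds == other.bonds and self.angles == other.angles
                and self.torsions == other.torsions)

    def torsion_mask(self) -> np.ndarray:
        mask = np.zeros(self.n, dtype=bool)
        mask[len(self.bonds) + len(self.angles):] = True
        return mask

    def dump(self, path: str | Path) -> None:
        """Text table of the coordinate definitions and current values."""
        with open(path, "w") as fh:
            fh.write("kind\tindices\tvalue\n")
            for kind, tup, val in zip(self.kinds, self.definitions, self.values):
                fh.write(f"{kind}\t{'-'.join(map(str, tup))}\t{val:.10f}\n")


def _coordinate_value(coords: np.ndarray, tup: tuple[int, ...]) -> float:
    if len(tup) == 2:
        return bond_value(coords, *tup)
    if len(tup) == 3:
        return angle_value(coords, *tup)
    return torsion_value(coords, *tup)


def ric_values(ric: InternalCoordinateSet,
               structure: AtomicStructure | np.ndarray) -> InternalCoordinateSet:
    """The same coordinate definitions re-valued on another geometry."""
    coords = (structure.coords if isinstance(structure, AtomicStructure)
              else np.asarray(structure, dtype=float))
    vals = np.array([_coordinate_value(coords, t) for t in ric.definitions])
    return InternalCoordinateSet(ric.bonds, ric.angles, ric.torsions, vals)


def build_ric(structure: AtomicStructure,
              bonds: Sequence[tuple[int, int]],
              linear_threshold_deg: float = 5.0) -> InternalCoordinateSet:
    """Construct the full redundant coordinate set from a bond list.

    Angles are all bond pairs sharing an atom (the shared atom is the apex);
    torsions are all i–j–k–l paths over three distinct bonds. Torsions whose
    central bendings come within ``linear_threshold_deg`` of 0° or 180° are
    excluded because their Wilson rows diverge. Output order is deterministic:
    each coordinate class sorted lexicographically by its index tuple.
    """
    if not bonds:
        raise ValueError("empty bond list")
    coords = structure.coords
    n = structure.n_atoms
    bond_set = {tuple(sorted(b)) for b in bonds}
    for (i, j) in bond_set:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise ValueError(f"invalid bond ({i}, {j})")
    neighbors: dict[int, set[int]] = {a: set() for a in range(n)}
    for (i, j) in bond_set:
        neighbors[i].add(j)
        neighbors[j].add(i)

    angles = []
    for apex in range(n):
        nbrs = sorted(neighbors[apex])
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                angles.append((nbrs[a], apex, nbrs[b]))

    thresh = np.deg2rad(linear_threshold_deg)

    def near_linear(i: int, j: int, k: int) -> bool:
        ang = angle_value(coords, i, j, k)
        return ang < thresh or ang > np.pi - thresh

    torsions = []
    for (j, k) in sorted(bond_set):
        for i in sorted(neighbors[j] - {k}):
            for l in sorted(neighbors[k] - {j}):
                if i == l:
                    continue
                if near_linear(i, j, k) or near_linear(j, k, l):
                    continue
                torsions.append((i, j, k, l))

    ric = InternalCoordinateSet(
        bonds=tuple(sorted(bond_set)),
        angles=tuple(sorted(angles)),
        torsions=tuple(sorted(torsions)),
    )
    return ric_values(ric, structure)


def delta_q(strained: InternalCoordinateSet,
            relaxed: InternalCoordinateSet) -> np.ndarray:
    """Per-coordinate displacement Δq = q_strained − q_relaxed.

    Torsion differences are wrapped into (−π, π] so that a crossing of the
    ±180° seam yields the short-arc difference.
    """
    if not strained.same_definitions(relaxed):
        raise ValueError("coordinate definitions differ between the two sets")
    dq = strained.values - relaxed.values
    mask = strained.torsion_mask()
    wrapped = np.mod(dq[mask] + np.pi, 2.0 * np.pi) - np.pi
    wrapped[wrapped == -np.pi] = np.pi
    dq[mask] = wrapped
    return dq


def wilson_b(structure: AtomicStructure,
             ric: InternalCoordinateSet) -> np.ndarray:
    """Wilson B matrix: row i holds ∂q_i/∂x over all 3N Cartesians."""
    coords = structure.coords
    n3 = 3 * structure.n_atoms
    B = np.zeros((ric.n, n3))
    for row, tup in enumerate(ric.definitions):
        if len(tup) == 2:
            grads = _bond_grad(coords, *tup)
        elif len(tup) == 3:
            grads = _angle_grad(coords, *tup)
        else:
            grads = _torsion_grad(coords, *tup)
        for atom, g in grads.items():
            B[row, 3 * atom:3 * atom + 3] = g
    return B
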