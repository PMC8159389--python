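"""Structure / trajectory I/O, bond detection, and per-bond scalar export.

All coordinates are Å. Multi-frame XYZ and multi-MODEL PDB are the two
trajectory formats; Hessians and gradients travel as whitespace-delimited
text matrices with a one-line header. PDB handling is delegated to biotite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .constants import COVALENT_RADII, normalize_element

logger = logging.getLogger(__name__)

__all__ = [
    "AtomicStructure",
    "Trajectory",
    "ParseError",
    "read_xyz",
    "write_xyz",
    "read_pdb",
    "write_pdb",
    "detect_bonds",
    "write_bond_scalars_pdb",
    "read_matrix",
    "write_matrix",
]


class ParseError(ValueError):
    """Raised for malformed structure or matrix files."""


@dataclass
class AtomicStructure:
    """A molecular geometry: element symbols plus Cartesian coordinates in Å.

    Optional per-atom labels (``atom_names``) and residue assignments
    (``residue_ids`` as ``(residue number, residue name)`` pairs) are carried
    through I/O; ``frame_time`` is a time stamp in ps for trajectory frames.
    """

    elements: tuple[str, ...]
    coords: np.ndarray
    atom_names: tuple[str, ...] | None = None
    residue_ids: tuple[tuple[int, str], ...] | None = None
    frame_time: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.elements = tuple(normalize_element(e) for e in self.elements)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.elements)} elements"
            )
        if self.atom_names is not None:
            self.atom_names = tuple(self.atom_names)
            if len(self.atom_names) != len(self.elements):
                raise ValueError("atom_names length mismatch")
        if self.residue_ids is not None:
            self.residue_ids = tuple((int(i), str(n)) for i, n in self.residue_ids)
            if len(self.residue_ids) != len(self.elements):
                raise ValueError("residue_ids length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def with_coords(self, coords: np.ndarray, **overrides) -> "AtomicStructure":
        """Copy of this structure with new coordinates (labels preserved)."""
        kwargs = dict(
            elements=self.elements,
            coords=np.array(coords, dtype=float),
            atom_names=self.atom_names,
            residue_ids=self.residue_ids,
            frame_time=self.frame_time,
            metadata=dict(self.metadata),
        )
        kwargs.update(overrides)
        return AtomicStructure(**kwargs)

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[j] - self.coords[i]))


@dataclass
class Trajectory:
    """Ordered frames sharing one element list; frame times non-decreasing."""

    frames: list[AtomicStructure]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        ref = self.frames[0].elements
        for k, fr in enumerate(self.frames):
            if fr.elements != ref:
                raise ValueError(
                    f"frame {k} element list differs from frame 0 "
                    f"({len(fr.elements)} vs {len(ref)} atoms)"
                )
        times = [fr.frame_time for fr in self.frames if fr.frame_time is not None]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[AtomicStructure]:
        return iter(self.frames)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return Trajectory(self.frames[idx])
        return self.frames[idx]

    @property
    def times(self) -> np.ndarray:
        return np.array(
            [fr.frame_time if fr.frame_time is not None else float(k)
             for k, fr in enumerate(self.frames)]
        )


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> Trajectory:
    """Read a (multi-frame) XYZ file.

    A comment line containing ``time=<float>`` sets the frame time in ps.
    All frames must declare the same atom count; parse failures report the
    offending line number.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[AtomicStructure] = []
    ln = 0
    n_lines = len(lines)
    while ln < n_lines:
        if not lines[ln].strip():  # trailing blank lines
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise ParseError(
                f"{path}: line {ln + 1}: expected atom count, got {lines[ln]!r}"
            ) from None
        if ln + 1 >= n_lines:
            raise ParseError(f"{path}: line {ln + 2}: missing comment line")
        comment = lines[ln + 1]
        frame_time = _time_from_comment(comment)
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        for a in range(natoms):
            idx = ln + 2 + a
            if idx >= n_lines:
                raise ParseError(
                    f"{path}: line {idx + 1}: expected {natoms} atom records, "
                    f"file ended after {a}"
                )
            parts = lines[idx].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {idx + 1}: expected 'element x y z', "
                    f"got {lines[idx]!r}"
                )
            try:
                elements.append(parts[0])
                coords[a] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(
                    f"{path}: line {idx + 1}: malformed coordinate in {lines[idx]!r}"
                ) from None
        frames.append(
            AtomicStructure(elements=tuple(elements), coords=coords,
                            frame_time=frame_time)
        )
        ln += 2 + natoms
    if not frames:
        raise ParseError(f"{path}: no frames found")
    try:
        return Trajectory(frames)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def _time_from_comment(comment: str) -> float | None:
    for token in comment.replace(",", " ").split():
        if token.startswith("time="):
            try:
                return float(token[5:])
            except ValueError:
                return None
    return None


def write_xyz(traj: Trajectory | AtomicStructure, path: str | Path) -> None:
    """Write a trajectory (or single structure) as multi-frame XYZ."""
    if isinstance(traj, AtomicStructure):
        traj = Trajectory([traj])
    with open(path, "w") as fh:
        for fr in traj:
            fh.write(f"{fr.n_atoms}\n")
            comment = "" if fr.frame_time is None else f"time={fr.frame_time:.6f}"
            fh.write(comment + "\n")
            for el, (x, y, z) in zip(fr.elements, fr.coords):
                fh.write(f"{el:<3s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


# ---------------------------------------------------------------------------
# PDB (via biotite)
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> Trajectory:
    """Read a (multi-MODEL) PDB file; residue and atom labels are kept.

    Only the first alternate location of each atom is retained (a warning is
    logged when alternates are dropped).
    """
    try:
        pdb = PDBFile.read(str(path))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = pdb.get_structure(model=None, altloc="first")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if stack.array_length() == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    elements = tuple(
        _resolve_element(el, name)
        for el, name in zip(stack.element, stack.atom_name)
    )
    atom_names = tuple(str(n) for n in stack.atom_name)
    residue_ids = tuple(
        (int(i), str(n)) for i, n in zip(stack.res_id, stack.res_name)
    )
    frames = [
        AtomicStructure(
            elements=elements,
            coords=np.asarray(stack.coord[m], dtype=float),
            atom_names=atom_names,
            residue_ids=residue_ids,
        )
        for m in range(stack.stack_depth())
    ]
    return Trajectory(frames)


def _resolve_element(element_field: str, atom_name: str) -> str:
    """Element from the PDB element column, falling back to the atom name."""
    for candidate in (element_field.strip(), ""):
        if candidate:
            try:
                return normalize_element(candidate)
            except ValueError:
                pass
    stripped = "".join(c for c in atom_name if c.isalpha())
    for length in (2, 1):
        try:
            return normalize_element(stripped[:length])
        except (ValueError, IndexError):
            continue
    raise ParseError(
        f"cannot resolve element for atom {atom_name!r} "
        f"(element column {element_field!r})"
    )


def _to_atom_array(structure: AtomicStructure,
                   b_factors: np.ndarray | None = None) -> bst.AtomArray:
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(structure.coords, dtype=np.float32)
    arr.element = np.array([e.upper() for e in structure.elements])
    if structure.atom_names is not None:
        arr.atom_name = np.array(structure.atom_names)
    else:
        arr.atom_name = np.array(
            [f"{e}{i + 1}" for i, e in enumerate(structure.elements)]
        )
    if structure.residue_ids is not None:
        arr.res_id = np.array([i for i, _ in structure.residue_ids])
        arr.res_name = np.array([nm for _, nm in structure.residue_ids])
    else:
        arr.res_id = np.ones(n, dtype=int)
        arr.res_name = np.array(["MOL"] * n)
    arr.chain_id = np.array(["A"] * n)
    arr.hetero = np.array([True] * n)
    arr.set_annotation(
        "b_factor",
        np.zeros(n) if b_factors is None else np.asarray(b_factors, dtype=float),
    )
    return arr


def write_pdb(traj: Trajectory | AtomicStructure, path: str | Path,
              b_factors: np.ndarray | None = None) -> None:
    """Write a trajectory as multi-MODEL PDB (single model for one structure)."""
    if isinstance(traj, AtomicStructure):
        traj = Trajectory([traj])
    pdb = PDBFile()
    if len(traj) == 1:
        pdb.set_structure(_to_atom_array(traj[0], b_factors))
    else:
        stack = bst.stack([_to_atom_array(fr, b_factors) for fr in traj])
        pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Bond detection
# ---------------------------------------------------------------------------

def detect_bonds(structure: AtomicStructure, scale: float = 1.3,
                 radii: Mapping[str, float] | None = None
                 ) -> list[tuple[int, int]]:
    """Covalent bonds by the distance criterion d(i,j) ≤ scale·(r_i + r_j).

    ``radii`` defaults to the package's Cordero-type covalent radii table.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    table = COVALENT_RADII if radii is None else radii
    missing = sorted({e for e in structure.elements if e not in table})
    if missing:
        raise ValueError(f"no covalent radius for element(s): {', '.join(missing)}")
    r = np.array([table[e] for e in structure.elements])
    diff = structure.coords[:, None, :] - structure.coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    cut = scale * (r[:, None] + r[None, :])
    ii, jj = np.nonzero(np.triu(dist <= cut, k=1))
    return sorted((int(i), int(j)) for i, j in zip(ii, jj))


# ---------------------------------------------------------------------------
# Per-bond scalar export (strain-on-bonds visualization)
# ---------------------------------------------------------------------------

def write_bond_scalars_pdb(structure: AtomicStructure,
                           bond_scalars: Mapping[tuple[int, int], float],
                           path: str | Path) -> None:
    """Export per-bond scalars for visualization.

    Writes a PDB whose B-factor column holds, per atom, the mean of the
    normalized scalars of its incident bonds (atoms in no bond get 0), plus a
    sidecar TSV ``<path>.bonds.tsv`` with the raw and normalized per-bond
    values. Scalars are clamped at 0 and normalized to [0, 1] by the maximum.
    """
    if not bond_scalars:
        raise ValueError("empty bond scalar map")
    n = structure.n_atoms
    for (i, j) in bond_scalars:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"bond ({i}, {j}) references invalid atom indices")
    clamped = {b: max(0.0, float(v)) for b, v in bond_scalars.items()}
    vmax = max(clamped.values())
    norm = {b: (v / vmax if vmax > 0 else 0.0) for b, v in clamped.items()}
    incident: list[list[float]] = [[] for _ in range(n)]
    for (i, j), v in norm.items():
        incident[i].append(v)
        incident[j].append(v)
    b_factors = np.array([np.mean(v) if v else 0.0 for v in incident])
    write_pdb(structure, path, b_factors=b_factors)
    sidecar = Path(str(path) + ".bonds.tsv")
    with open(sidecar, "w") as fh:
        fh.write("atom_i\tatom_j\tscalar\tnormalized\n")
        for (i, j) in sorted(bond_scalars):
            fh.write(f"{i}\t{j}\t{bond_scalars[(i, j)]:.10g}\t{norm[(i, j)]:.6f}\n")


# ---------------------------------------------------------------------------
# Plain-text matrices (Hessians, gradients)
# ---------------------------------------------------------------------------

def write_matrix(matrix: np.ndarray, path: str | Path, n_atoms: int,
                 units: str = "kJ/mol/A^2") -> None:
    """Write a matrix with a one-line header stating atom count and units."""
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    np.savetxt(path, m, header=f"natoms={n_atoms} units={units}", comments="# ")


def read_matrix(path: str | Path) -> tuple[np.ndarray, int, str]:
    """Read a matrix written by :func:`write_matrix`; returns (M, n_atoms, units)."""
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ParseError(f"{path}: line 1: missing '# natoms=... units=...' header")
    fields = dict(
        tok.split("=", 1) for tok in header.lstrip("# ").split() if "=" in tok
    )
    try:
        n_atoms = int(fields["natoms"])
    except (KeyError, ValueError):
        raise ParseError(f"{path}: line 1: header must state natoms=<int>") from None
    units = fields.get("units", "")
    matrix = np.atleast_2d(np.loadtxt(path))
    return matrix, n_atoms, units
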