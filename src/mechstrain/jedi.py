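"""Harmonic strain partitioning in redundant internal coordinates (JEDI).

The strain energy of a distorted geometry relative to its relaxed reference
is approximated by the quadratic form ½ Δqᵀ H_q Δq, with H_q the Cartesian
Hessian of the reference transformed into the redundant internal coordinate
space through the Moore–Penrose pseudoinverse of the Wilson B matrix. The
total is attributed to individual bonds, bendings and torsions by the
row-share rule E_i = ½ Δq_i (H_q Δq)_i, which splits every off-diagonal
coupling evenly between its two coordinates and therefore conserves the
total exactly. The gradient correction term is omitted because the reference
is taken at a local minimum; a warning is emitted if a supplied reference
gradient is not small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .internal_coords import InternalCoordinateSet

logger = logging.getLogger(__name__)

__all__ = ["StrainReport", "hessian_to_internal", "jedi_partition",
           "strain_to_bonds"]

#: Relative singular-value cutoff for the pseudoinverse of B. The redundant
#: coordinate set has an exact null space; this separates it from the range.
SVD_RCOND = 1e-8

#: Reference-gradient norm (kJ/mol/Å) above which the harmonic reference
#: assumption is considered violated and a warning is logged.
GRADIENT_WARN_NORM = 1.0


@dataclass
class StrainReport:
    """Per-internal-coordinate strain energies for one snapshot pair.

    ``energies`` are in kJ/mol; ``percents`` are 100·E_i/ΣE_i and are ``None``
    when the total is non-positive (flagged ``non_positive``). Individual
    energies may be negative through coupling terms; they are reported as-is.
    """

    ric: InternalCoordinateSet
    delta_q: np.ndarray
    energies: np.ndarray
    total: float
    percents: np.ndarray | None = None
    non_positive: bool = False
    snapshot_time: float | None = None

    @property
    def labels(self) -> tuple[str, ...]:
        return self.ric.labels

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per internal coordinate."""
        df = pd.DataFrame({
            "kind": self.ric.kinds,
            "indices": ["-".join(map(str, t)) for t in self.ric.definitions],
            "value": self.ric.values,
            "delta_q": self.delta_q,
            "energy_kj_mol": self.energies,
            "percent": (self.percents if self.percents is not None
                        else np.full(self.ric.n, np.nan)),
        })
        if self.snapshot_time is not None:
            df.insert(0, "time_ps", self.snapshot_time)
        return df

    def write_table(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def hessian_to_internal(h_cart: np.ndarray, b_matrix: np.ndarray,
                        rcond: float = SVD_RCOND) -> np.ndarray:
    """Transform a Cartesian Hessian into the RIC space.

    H_q = (B⁺)ᵀ H_x B⁺ with B⁺ the pseudoinverse of the Wilson matrix
    (singular values below ``rcond``·σ_max treated as zero); the result is
    symmetrized. Raises if B does not span all internal degrees of freedom.
    """
    h_cart = np.asarray(h_cart, dtype=float)
    b_matrix = np.atleast_2d(np.asarray(b_matrix, dtype=float))
    n3 = h_cart.shape[0]
    if h_cart.shape != (n3, n3):
        raise ValueError("Cartesian Hessian must be square")
    if b_matrix.shape[1] != n3:
        raise ValueError("B matrix column count does not match Hessian size")
    if not np.allclose(h_cart, h_cart.T, atol=1e-8 * max(1.0, np.abs(h_cart).max())):
        raise ValueError("Cartesian Hessian must be symmetric")
    n_atoms = n3 // 3
    expected_rank = max(3 * n_atoms - 6, 1) if n_atoms > 1 else 0
    svals = np.linalg.svd(b_matrix, compute_uv=False)
    rank = int(np.sum(svals > rcond * svals.max()))
    # 3N-5 internal dofs for a linear molecule; accept the smaller count only
    # when the geometry actually is linear (diatomics always are).
    if rank < expected_rank and not (n_atoms == 2 and rank >= 1):
        if rank < 3 * n_atoms - 5 or n_atoms > 2:
            raise ValueError(
                f"incomplete coordinate set: B rank {rank} < {expected_rank} "
                f"internal degrees of freedom"
            )
    b_pinv = np.linalg.pinv(b_matrix, rcond=rcond)
    h_q = b_pinv.T @ h_cart @ b_pinv
    return 0.5 * (h_q + h_q.T)


def jedi_partition(delta_q: np.ndarray, h_q: np.ndarray,
                   ric: InternalCoordinateSet,
                   snapshot_time: float | None = None) -> StrainReport:
    """Partition the harmonic strain ½ΔqᵀH_qΔq among internal coordinates.

    E_i = ½ Δq_i (H_q Δq)_i; Σ E_i equals the quadratic form exactly.
    """
    dq = np.asarray(delta_q, dtype=float)
    h_q = np.asarray(h_q, dtype=float)
    if h_q.shape != (dq.size, dq.size):
        raise ValueError("dimension mismatch between Δq and H_q")
    if ric.n != dq.size:
        raise ValueError("coordinate set size does not match Δq")
    energies = 0.5 * dq * (h_q @ dq)
    total = float(energies.sum())
    non_positive = total <= 0.0 and bool(np.any(dq != 0.0))
    if total > 0.0:
        percents = 100.0 * energies / total
    else:
        percents = None
        if non_positive:
            logger.warning("non-positive strain total %.3g kJ/mol; "
                           "percentages suppressed", total)
    return StrainReport(ric=ric, delta_q=dq, energies=energies, total=total,
                        percents=percents, non_positive=non_positive,
                        snapshot_time=snapshot_time)


def strain_to_bonds(report: StrainReport,
                    ric: InternalCoordinateSet | None = None
                    ) -> dict[tuple[int, int], float]:
    """Project a strain report onto bonds for visualization.

    Each bond keeps its own energy, receives half of every incident bending's
    energy (one share per leg) and a third of every incident torsion's energy
    (one share per consecutive bond). The map conserves the report total.
    Angle legs or torsion edges that are not themselves in the bond list
    contribute their share to a virtual bond entry, so conservation holds for
    any redundant set built by :func:`~mechstrain.internal_coords.build_ric`.
    """
    ric = report.ric if ric is None else ric
    if ric.n != report.energies.size:
        raise ValueError("report and coordinate set are inconsistent")
    out: dict[tuple[int, int], float] = {tuple(sorted(b)): 0.0 for b in ric.bonds}

    def add(i: int, j: int, amount: float) -> None:
        key = (min(i, j), max(i, j))
        out[key] = out.get(key, 0.0) + amount

    for tup, kind, e in zip(ric.definitions, ric.kinds, report.energies):
        e = float(e)
        if kind == "bond":
            add(tup[0], tup[1], e)
        elif kind == "angle":
            i, j, k = tup
            add(i, j, e / 2.0)
            add(j, k, e / 2.0)
        else:
            i, j, k, l = tup
            add(i, j, e / 3.0)
            add(j, k, e / 3.0)
            add(k, l, e / 3.0)
    return out
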