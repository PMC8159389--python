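"""Hydrogen-bond prevalence and distance analytics over trajectories.

The NH⋯S hydrogen-bond criterion is purely geometric: a backbone amide
hydrogen of a listed donor residue within 3.0 Å of a sulfur acceptor counts
as one hydrogen bond (no angle criterion). Prevalence is summarized as the
fraction of frames showing 0, 1, 2, … bonds, optionally per acceptor, and as
means over equally sized trajectory windows for a time-resolved view.
Distance series (e.g. Fe–S distances of strained geometries) get ordinary
least-squares trend lines with a pointwise confidence band of the mean
response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .geom_io import AtomicStructure, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "HBondSpec",
    "DistanceSeries",
    "count_hbonds",
    "hbond_histogram",
    "windowed_mean",
    "linear_fit_ci",
    "LinearFit",
    "distance_series",
]

#: atom names accepted as the backbone amide hydrogen
_AMIDE_H_NAMES = ("H", "HN")

DEFAULT_CUTOFF = 3.0  # Å, S–H distance criterion


def _parse_residue(res) -> tuple[int, str]:
    """Accept ('LYS', 6)-style tuples or compact 'Lys6' strings."""
    if isinstance(res, str):
        name = "".join(c for c in res if c.isalpha())
        num = "".join(c for c in res if c.isdigit())
        if not name or not num:
            raise ValueError(f"cannot parse residue identifier {res!r}")
        return int(num), name.upper()
    num, name = res
    return int(num), str(name).upper()


@dataclass(frozen=True)
class HBondSpec:
    """Acceptor sulfur atoms, donor residues, and the distance cutoff (Å)."""

    acceptor_atoms: tuple[int, ...]
    donor_residues: tuple[tuple[int, str], ...]
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        object.__setattr__(self, "acceptor_atoms",
                           tuple(int(i) for i in self.acceptor_atoms))
        object.__setattr__(self, "donor_residues",
                           tuple(_parse_residue(r) for r in self.donor_residues))


def _amide_hydrogens(frame: AtomicStructure,
                     donors: Sequence[tuple[int, str]]) -> list[int]:
    if frame.residue_ids is None or frame.atom_names is None:
        raise ValueError("frame needs residue and atom labels for H-bond analysis")
    hydrogens = []
    for rid in donors:
        found = [
            idx for idx, (res, name) in
            enumerate(zip(frame.residue_ids, frame.atom_names))
            if res == rid and name.upper() in _AMIDE_H_NAMES
        ]
        if not found:
            logger.warning("donor residue %s%d has no amide hydrogen; skipped",
                           rid[1], rid[0])
            continue
        hydrogens.extend(found)
    return hydrogens


def count_hbonds(frame: AtomicStructure,
                 spec: HBondSpec) -> dict[int, int]:
    """Hydrogen-bond count per acceptor sulfur atom in one frame."""
    hydrogens = _amide_hydrogens(frame, spec.donor_residues)
    counts: dict[int, int] = {}
    for acc in spec.acceptor_atoms:
        s = frame.coords[acc]
        n = sum(
            1 for h in hydrogens
            if float(np.linalg.norm(frame.coords[h] - s)) <= spec.cutoff
        )
        counts[acc] = n
    return counts


def hbond_histogram(traj: Trajectory, spec: HBondSpec,
                    pooled: bool = True
                    ) -> dict[int, float] | dict[int, dict[int, float]]:
    """Fraction of frames with 0, 1, 2, … hydrogen bonds.

    With ``pooled=True`` the counts of all acceptors are summed per frame
    before histogramming; otherwise one histogram per acceptor is returned.
    Fractions sum to 1 in every histogram.
    """
    per_frame = [count_hbonds(fr, spec) for fr in traj]
    n = len(per_frame)

    def hist(values: Sequence[int]) -> dict[int, float]:
        out: dict[int, float] = {}
        for v in values:
            out[v] = out.get(v, 0) + 1
        return {k: c / n for k, c in sorted(out.items())}

    if pooled:
        return hist([sum(c.values()) for c in per_frame])
    return {acc: hist([c[acc] for c in per_frame])
            for acc in spec.acceptor_atoms}


def windowed_mean(values: Sequence[float], n_windows: int) -> np.ndarray:
    """Means over ``n_windows`` contiguous, as-equal-as-possible blocks.

    When the frame count is not divisible, earlier windows take the extra
    frames (the convention behind 20-window prevalence plots).
    """
    values = np.asarray(values, dtype=float)
    if n_windows <= 0:
        raise ValueError("n_windows must be positive")
    if n_windows > values.size:
        raise ValueError("more windows than frames")
    return np.array([block.mean() for block in np.array_split(values, n_windows)])


# ---------------------------------------------------------------------------
# Distance series and linear trends
# ---------------------------------------------------------------------------

@dataclass
class DistanceSeries:
    """One labeled distance as a function of time (ps, Å)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ps": self.times, "distance_A": self.values,
             "label": self.label})


def distance_series(traj: Trajectory, pairs: Mapping[str, tuple[int, int]]
                    ) -> list[DistanceSeries]:
    """Per-frame distances for labeled atom pairs (e.g. ``{"Fe-S_5": (0, 1)}``)."""
    times = traj.times
    out = []
    for label, (i, j) in pairs.items():
        vals = np.array([fr.distance(i, j) for fr in traj])
        out.append(DistanceSeries(times=times, values=vals, label=label))
    return out


@dataclass
class LinearFit:
    slope: float
    intercept: float
    times: np.ndarray
    predicted: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    confidence: float
    slope_ci: tuple[float, float] = (float("nan"), float("nan"))


def linear_fit_ci(series: DistanceSeries,
                  confidence: float = 0.95) -> LinearFit:
    """OLS trend line with the pointwise t-based CI of the mean response."""
    t = series.times
    y = series.values
    if t.size < 3:
        raise ValueError("need at least 3 points for a fit")
    if np.ptp(t) == 0:
        raise ValueError("zero time variance; cannot fit a trend")
    x = sm.add_constant(t)
    fit = sm.OLS(y, x).fit()
    pred = fit.get_prediction(x)
    ci = pred.conf_int(alpha=1.0 - confidence)
    param_ci = fit.conf_int(alpha=1.0 - confidence)
    return LinearFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        times=t,
        predicted=np.asarray(pred.predicted_mean),
        ci_lower=np.asarray(ci[:, 0]),
        ci_upper=np.asarray(ci[:, 1]),
        confidence=confidence,
        slope_ci=(float(param_ci[1, 0]), float(param_ci[1, 1])),
    )
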