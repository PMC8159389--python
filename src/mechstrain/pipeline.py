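"""The per-snapshot strain-analysis workflow.

For every trajectory frame: optionally carve out the quantum region (the
selected residues plus the iron center, hydrogen-capping every cut bond),
produce a strained/relaxed geometry pair (constrained optimization at the
frame positions, then an unconstrained tiny-step relaxation to the nearest
local minimum), build the redundant internal coordinates on the relaxed
reference, transform its Hessian, and partition the harmonic strain. The
per-snapshot reports are aggregated into a mean-percentage table with a 95%
confidence interval (normal approximation over snapshots) and a
time-resolved percentage table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geom_io import AtomicStructure, Trajectory, detect_bonds
from .internal_coords import InternalCoordinateSet, build_ric, delta_q, ric_values, wilson_b
from .jedi import StrainReport, hessian_to_internal, jedi_partition
from .mechanochemistry import Calculator, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "SnapshotPair",
    "PipelineError",
    "extract_qm_region",
    "make_pair",
    "JediRunConfig",
    "JediRunResult",
    "run_trajectory_jedi",
    "force_bearing_scaffold",
]

#: standard backbone atom names used for the frozen-atom selection
BACKBONE_ATOM_NAMES = ("N", "CA", "C", "O")

#: cap-hydrogen distance from the kept atom, by kept-atom element (Å)
CAP_DISTANCES = {"C": 1.09, "N": 1.01}

#: tiny max step (Å) for the nearest-local-minimum relaxation
TINY_MAX_STEP = 0.02


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class SnapshotPair:
    """A strained geometry and its relaxed reference for one snapshot."""

    strained: AtomicStructure
    relaxed: AtomicStructure
    snapshot_time: float | None = None
    provenance: dict = field(default_factory=dict)


def extract_qm_region(frame: AtomicStructure,
                      residue_selection: Sequence,
                      cap_bonds: Sequence[tuple[int, int]] = (),
                      ) -> AtomicStructure:
    """Carve out the selected residues (plus any Fe) and hydrogen-cap cuts.

    ``cap_bonds`` lists (kept_atom, removed_atom) pairs; each cut bond is
    saturated by a hydrogen on the original bond vector at 1.09 Å from a
    kept carbon or 1.01 Å from a kept nitrogen. Link atoms are labelled
    ``HL<n>`` and listed in ``metadata['link_atoms']``.
    """
    if not residue_selection:
        raise ValueError("empty residue selection")
    if frame.residue_ids is None:
        raise ValueError("frame has no residue labels")
    selection = {(int(i), str(n).upper()) for i, n in
                 (r if not isinstance(r, str) else _split_res(r)
                  for r in residue_selection)}
    keep = [
        idx for idx, rid in enumerate(frame.residue_ids)
        if (rid[0], rid[1].upper()) in selection or frame.elements[idx] == "Fe"
    ]
    keep_set = set(keep)
    for kept, removed in cap_bonds:
        if kept not in keep_set:
            raise ValueError(f"cap bond ({kept}, {removed}): kept atom not in selection")
        if removed in keep_set:
            raise ValueError(f"cap bond ({kept}, {removed}): both atoms kept")

    new_index = {old: new for new, old in enumerate(keep)}
    elements = [frame.elements[i] for i in keep]
    coords = [frame.coords[i] for i in keep]
    names = list(frame.atom_names) if frame.atom_names is not None else None
    atom_names = [names[i] for i in keep] if names else [
        f"{frame.elements[i]}{i}" for i in keep]
    residues = [frame.residue_ids[i] for i in keep]

    link_atoms = []
    for n_link, (kept, removed) in enumerate(cap_bonds, start=1):
        vec = frame.coords[removed] - frame.coords[kept]
        norm = np.linalg.norm(vec)
        if norm < 1e-8:
            raise ValueError(f"cap bond ({kept}, {removed}) has zero length")
        dist = CAP_DISTANCES.get(frame.elements[kept])
        if dist is None:
            logger.warning("no cap distance for element %s; using 1.09 Å",
                           frame.elements[kept])
            dist = 1.09
        elements.append("H")
        coords.append(frame.coords[kept] + dist * vec / norm)
        atom_names.append(f"HL{n_link}")
        residues.append(frame.residue_ids[kept])
        link_atoms.append(len(elements) - 1)

    out = AtomicStructure(
        elements=tuple(elements), coords=np.array(coords),
        atom_names=tuple(atom_names), residue_ids=tuple(residues),
        frame_time=frame.frame_time,
    )
    out.metadata.update(link_atoms=link_atoms, index_map=new_index)
    return out


def _split_res(token: str) -> tuple[int, str]:
    name = "".join(c for c in token if c.isalpha())
    num = "".join(c for c in token if c.isdigit())
    return int(num), name.upper()


def make_pair(snapshot: AtomicStructure, calc: Calculator,
              frozen_atoms: Sequence[int],
              max_step: float = 0.3,
              max_iterations: int = 2000) -> SnapshotPair:
    """Strained/relaxed pair for one snapshot.

    The strained geometry is the constrained minimum with ``frozen_atoms``
    held at their snapshot positions; the relaxed reference is an
    unconstrained follow-up optimization from it with a tiny step cap, which
    lands in the nearest local minimum.
    """
    if not frozen_atoms:
        raise ValueError("frozen_atoms must be non-empty for the strained stage")
    strained_res = optimize(calc, snapshot, frozen_atoms=frozen_atoms,
                            max_step=max_step, max_iterations=max_iterations)
    if not strained_res.converged:
        raise PipelineError("strained", "constrained optimization did not converge")
    relaxed_res = optimize(calc, strained_res.structure,
                           max_step=TINY_MAX_STEP,
                           max_iterations=10 * max_iterations)
    if not relaxed_res.converged:
        raise PipelineError("relaxed", "tiny-step relaxation did not converge")
    return SnapshotPair(
        strained=strained_res.structure,
        relaxed=relaxed_res.structure,
        snapshot_time=snapshot.frame_time,
        provenance={
            "strained_energy": strained_res.energy,
            "relaxed_energy": relaxed_res.energy,
            "frozen_atoms": list(frozen_atoms),
            "stages": ["constrained", "tiny-step-relax"],
        },
    )


@dataclass
class JediRunConfig:
    """Configuration of the trajectory-level strain analysis.

    ``frozen_atoms`` plays the role of the fixed backbone during the
    strained-stage optimization. ``scissile_bond`` (with
    ``rupture_length_factor``) excludes frames already past rupture from the
    aggregate statistics; ``stride`` thins the frame set.
    """

    calculator: Calculator
    frozen_atoms: tuple[int, ...]
    bonds: tuple[tuple[int, int], ...] | None = None
    bond_scale: float = 1.3
    residue_selection: tuple | None = None
    cap_bonds: tuple[tuple[int, int], ...] = ()
    scissile_bond: tuple[int, int] | None = None
    rupture_length_factor: float = 1.5
    stride: int = 1
    skip_failed: bool = False
    confidence_z: float = 1.96


@dataclass
class JediRunResult:
    reports: list[StrainReport]
    mean_table: pd.DataFrame
    time_table: pd.DataFrame
    excluded_frames: list[int]
    failed_frames: list[int]
    pairs: list[SnapshotPair]


def run_trajectory_jedi(frames: Trajectory,
                        config: JediRunConfig) -> JediRunResult:
    """Per-snapshot JEDI along a trajectory, plus aggregate tables.

    Returns per-snapshot strain reports, the per-coordinate mean strain
    percentage with its 95% confidence interval over snapshots, and the
    time-resolved percentage table. Frames whose scissile bond exceeds the
    rupture-length threshold are excluded from the aggregates (they remain in
    ``reports``).
    """
    calc = config.calculator
    reports: list[StrainReport] = []
    pairs: list[SnapshotPair] = []
    excluded: list[int] = []
    failed: list[int] = []
    ric_ref: InternalCoordinateSet | None = None
    bonds = config.bonds

    work = list(frames)[:: max(1, config.stride)]
    for k, frame in enumerate(work):
        try:
            region = frame
            if config.residue_selection:
                region = extract_qm_region(frame, config.residue_selection,
                                           config.cap_bonds)
            pair = make_pair(region, calc, config.frozen_atoms)
            if bonds is None:
                bonds = tuple(detect_bonds(pair.relaxed, scale=config.bond_scale))
            ric_relaxed = build_ric(pair.relaxed, list(bonds))
            if ric_ref is None:
                ric_ref = ric_relaxed
            elif not ric_relaxed.same_definitions(ric_ref):
                # topology must stay fixed for comparable reports
                ric_relaxed = ric_values(ric_ref, pair.relaxed)
            ric_strained = ric_values(ric_relaxed, pair.strained)
            b_mat = wilson_b(pair.relaxed, ric_relaxed)
            h_cart = calc.hessian(pair.relaxed.coords)
            h_q = hessian_to_internal(h_cart, b_mat)
            dq = delta_q(ric_strained, ric_relaxed)
            report = jedi_partition(dq, h_q, ric_relaxed,
                                    snapshot_time=pair.snapshot_time)
            reports.append(report)
            pairs.append(pair)
        except Exception as exc:
            if not config.skip_failed:
                raise PipelineError("frame", f"frame {k}: {exc}") from exc
            logger.warning("frame %d failed (%s); skipped", k, exc)
            failed.append(k)
            continue
        if config.scissile_bond is not None:
            i, j = config.scissile_bond
            ref_len = reports[0].ric.values[
                reports[0].ric.bonds.index(tuple(sorted((i, j))))]
            if pair.strained.distance(i, j) > config.rupture_length_factor * ref_len:
                excluded.append(len(reports) - 1)

    mean_table, time_table = _aggregate(reports, excluded, config.confidence_z)
    return JediRunResult(reports=reports, mean_table=mean_table,
                         time_table=time_table, excluded_frames=excluded,
                         failed_frames=failed, pairs=pairs)


def _aggregate(reports: list[StrainReport], excluded: list[int],
               z: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    if not reports:
        raise ValueError("no successful snapshots")
    ric = reports[0].ric
    labels = ric.labels
    rows, times = [], []
    for idx, rep in enumerate(reports):
        if idx in excluded:
            continue
        pct = (rep.percents if rep.percents is not None
               else np.zeros(ric.n))
        rows.append(pct)
        times.append(rep.snapshot_time if rep.snapshot_time is not None else idx)
    data = np.array(rows) if rows else np.zeros((0, ric.n))
    time_table = pd.DataFrame(data, columns=labels,
                              index=pd.Index(times, name="time_ps"))
    mean = data.mean(axis=0) if len(rows) else np.zeros(ric.n)
    se = (data.std(axis=0, ddof=1) / np.sqrt(len(rows))
          if len(rows) > 1 else np.zeros(ric.n))
    mean_table = pd.DataFrame({
        "kind": ric.kinds,
        "indices": ["-".join(map(str, t)) for t in ric.definitions],
        "mean_percent": mean,
        "ci_halfwidth": z * se,
    }, index=pd.Index(labels, name="coordinate"))
    return mean_table, time_table


def force_bearing_scaffold(mean_table: pd.DataFrame,
                           threshold_percent: float = 5.0) -> list[str]:
    """Coordinates whose mean strain percentage exceeds the threshold —
    operationally, the load path between the pulling attachment points."""
    sel = mean_table[mean_table["mean_percent"] > threshold_percent]
    return list(sel.index)
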