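import numpy as np
import pytest

from mechstrain.geom_io import AtomicStructure, Trajectory
from mechstrain.synthetic import DEFAULT_DONOR_RESIDUES, generate_hbond_fixture
from mechstrain.trajectory_analysis import (
    DistanceSeries,
    HBondSpec,
    count_hbonds,
    distance_series,
    hbond_histogram,
    linear_fit_ci,
    windowed_mean,
)

from conftest import random_rotation


def _frame_with_donors(distances):
    """One sulfur acceptor plus one amide H per donor residue at the given
    distances (Å)."""
    donors = DEFAULT_DONOR_RESIDUES[:len(distances)]
    elements = ["S"] + ["N", "H"] * len(donors)
    names = ["SG"]
    residues = [(5, "CYS")]
    coords = [[0.0, 0.0, 0.0]]
    for k, (rid, d) in enumerate(zip(donors, distances)):
        direction = np.eye(3)[k % 3]
        coords.append((d + 1.0) * direction)  # N behind the H
        coords.append(d * direction)
        names += ["N", "H"]
        residues += [rid, rid]
    return AtomicStructure(tuple(elements), np.array(coords),
                           atom_names=tuple(names), residue_ids=tuple(residues))


def _spec(n_donors=9, cutoff=3.0, acceptors=(0,)):
    return HBondSpec(acceptor_atoms=acceptors,
                     donor_residues=DEFAULT_DONOR_RESIDUES[:n_donors],
                     cutoff=cutoff)


class TestCountHbonds:
    @pytest.mark.parametrize("distances,expected", [
        ((2.5,), 1),
        ((3.01,), 0),            # strictly beyond the 3.0 Å criterion
        ((3.0,), 1),             # boundary is inclusive
        ((2.0, 2.9, 3.5), 2),
    ])
    def test_distance_criterion(self, distances, expected):
        frame = _frame_with_donors(distances)
        counts = count_hbonds(frame, _spec(len(distances)))
        assert counts[0] == expected

    def test_rigid_motion_invariance(self, rng):
        frame = _frame_with_donors((2.2, 2.8, 3.4, 2.95))
        spec = _spec(4)
        before = count_hbonds(frame, spec)
        R = random_rotation(rng)
        moved = frame.with_coords(frame.coords @ R.T + [10.0, -4.0, 2.0])
        assert count_hbonds(moved, spec) == before

    def test_donor_without_amide_h_skipped_with_warning(self, caplog):
        frame = _frame_with_donors((2.5,))
        spec = _spec(2)  # second donor has no atoms in the frame
        with caplog.at_level("WARNING"):
            counts = count_hbonds(frame, spec)
        assert counts[0] == 1
        assert "no amide hydrogen" in caplog.text

    def test_string_donor_identifiers_accepted(self):
        frame = _frame_with_donors((2.5,))
        spec = HBondSpec(acceptor_atoms=(0,), donor_residues=("Lys6",))
        assert count_hbonds(frame, spec)[0] == 1


class TestHbondHistogram:
    def test_fractions_from_known_counts(self):
        frames = [_frame_with_donors(d) for d in
                  ((3.5, 3.5), (2.5, 3.5), (2.5, 3.6), (2.2, 2.8))]
        traj = Trajectory(frames)
        hist = hbond_histogram(traj, _spec(2))
        assert hist == {0: 0.25, 1: 0.5, 2: 0.25}

    def test_all_zero_fixture(self):
        traj = Trajectory([_frame_with_donors((4.0,))] * 3)
        assert hbond_histogram(traj, _spec(1)) == {0: 1.0}

    def test_pooled_vs_per_acceptor_agree_with_enumeration(self, rng):
        layout = [(0, 2), (1, 1), (3, 0), (2, 2), (0, 0)]
        traj = generate_hbond_fixture(layout, seed=5)
        spec = HBondSpec(acceptor_atoms=(0, 1),
                         donor_residues=DEFAULT_DONOR_RESIDUES)
        pooled = hbond_histogram(traj, spec, pooled=True)
        per = hbond_histogram(traj, spec, pooled=False)
        totals = [a + b for a, b in layout]
        assert pooled == {t: totals.count(t) / len(layout) for t in set(totals)}
        firsts = [a for a, _ in layout]
        assert per[0] == {v: firsts.count(v) / len(layout) for v in set(firsts)}

    def test_fractions_sum_to_one(self, rng):
        layout = rng.integers(0, 4, size=(30, 2)).tolist()
        traj = generate_hbond_fixture(layout, seed=11)
        spec = HBondSpec(acceptor_atoms=(0, 1),
                         donor_residues=DEFAULT_DONOR_RESIDUES)
        for hist in (hbond_histogram(traj, spec),
                     *hbond_histogram(traj, spec, pooled=False).values()):
            assert sum(hist.values()) == pytest.approx(1.0, abs=1e-12)


class TestWindowedMean:
    @pytest.mark.parametrize("values,n,expected", [
        (list(range(20)), 20, list(range(20))),          # identity
        ([3.0] * 17, 5, [3.0] * 5),                      # constant
        (list(range(10)), 2, [2.0, 7.0]),                # arithmetic blocks
        (list(range(10)), 3, [1.5, 5.0, 8.0]),           # remainder first
    ])
    def test_block_means(self, values, n, expected):
        np.testing.assert_allclose(windowed_mean(values, n), expected)

    def test_single_window_is_global_mean(self, rng):
        v = rng.normal(size=37)
        assert windowed_mean(v, 1)[0] == pytest.approx(v.mean())

    def test_invalid_window_counts(self):
        with pytest.raises(ValueError):
            windowed_mean([1.0, 2.0], 0)
        with pytest.raises(ValueError):
            windowed_mean([1.0, 2.0], 3)


class TestLinearFit:
    def test_exact_line_zero_width_band(self):
        t = np.arange(10.0)
        fit = linear_fit_ci(DistanceSeries(t, 2.0 * t + 1.0))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        np.testing.assert_allclose(fit.ci_upper - fit.ci_lower, 0.0, atol=1e-8)

    def test_constant_series_zero_slope(self):
        fit = linear_fit_ci(DistanceSeries(np.arange(5.0), np.full(5, 2.3)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_slope_ci_coverage(self):
        # 95% CI should cover the true slope in >= 93/100 seeded replicates
        rng = np.random.default_rng(2024)
        t = np.linspace(0.0, 10.0, 25)
        hits = 0
        for _ in range(100):
            y = 0.8 + 0.05 * t + rng.normal(0, 0.1, t.size)
            fit = linear_fit_ci(DistanceSeries(t, y))
            lo, hi = fit.slope_ci
            hits += lo <= 0.05 <= hi
        assert hits >= 93

    def test_zero_time_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            linear_fit_ci(DistanceSeries(np.zeros(5), np.arange(5.0)))


class TestDistanceSeries:
    def test_labeled_pairs_from_trajectory(self, toy_cluster):
        structure, _ = toy_cluster
        frames = [structure.with_coords(structure.coords * (1 + 0.01 * k),
                                        frame_time=float(k))
                  for k in range(4)]
        series = distance_series(Trajectory(frames),
                                 {"Fe-S_5": (0, 1), "Fe-S_41": (0, 2)})
        assert [s.label for s in series] == ["Fe-S_5", "Fe-S_41"]
        assert series[0].values[0] == pytest.approx(2.3)
        assert series[0].values[-1] == pytest.approx(2.3 * 1.03)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            DistanceSeries(np.array([0.0, 2.0, 1.0]), np.ones(3))
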