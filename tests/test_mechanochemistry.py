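import numpy as np
import pytest

from mechstrain.constants import NN_TO_KJ_PER_MOL_PER_ANGSTROM
from mechstrain.geom_io import AtomicStructure
from mechstrain.internal_coords import angle_value
from mechstrain.mechanochemistry import (
    MorseBondParams,
    RuptureError,
    efei_wrap,
    find_rupture_force,
    harmonic_diatomic_calculator,
    morse_diatomic_calculator,
    optimize,
    restoring_force,
    toy_cluster_calculator,
)
from mechstrain.synthetic import build_toy_cluster

MORSE = MorseBondParams(de=90.0, beta_nm=30.0, r0=2.3)
#: analytic maximum of the Morse restoring force, D_e·β/2
F_MAX_NN = MORSE.max_force_nn


class TestCalculatorContract:
    @pytest.mark.parametrize("which", ["morse", "cluster"])
    def test_gradient_matches_energy_finite_difference(self, which, toy_cluster,
                                                       toy_calc, rng):
        if which == "morse":
            calc = morse_diatomic_calculator()
            coords = np.array([[0.0, 0, 0], [0.3, 0.4, 2.2]])
        else:
            calc = toy_calc
            coords = toy_cluster[0].coords + rng.normal(0, 0.05, (21, 3))
        g = calc.gradient(coords)
        h = 1e-5
        flat = coords.reshape(-1)
        for col in rng.choice(flat.size, min(8, flat.size), replace=False):
            xp, xm = flat.copy(), flat.copy()
            xp[col] += h
            xm[col] -= h
            fd = (calc.energy(xp.reshape(-1, 3))
                  - calc.energy(xm.reshape(-1, 3))) / (2 * h)
            assert g[col] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_hessian_symmetric(self, toy_calc, toy_cluster):
        h = toy_calc.hessian(toy_cluster[0].coords)
        np.testing.assert_allclose(h, h.T, atol=1e-10)


class TestToyClusterCalculator:
    def test_reference_geometry_is_stationary(self, toy_cluster, toy_calc):
        g = toy_calc.gradient(toy_cluster[0].coords)
        assert np.abs(g).max() < 1e-6

    def test_energy_rotation_invariant(self, toy_cluster, toy_calc, rng):
        from conftest import random_rotation
        structure, _ = toy_cluster
        R = random_rotation(rng)
        e0 = toy_calc.energy(structure.coords)
        e1 = toy_calc.energy(structure.coords @ R.T + [1.0, 2.0, 3.0])
        assert e1 == pytest.approx(e0, abs=1e-10)

    def test_hessian_has_six_rigid_modes(self, toy_cluster, toy_calc):
        w = np.linalg.eigvalsh(toy_calc.hessian(toy_cluster[0].coords))
        assert np.sum(np.abs(w) < 1e-6) == 6
        assert w[6] > 0.1  # all internal modes stiff

    @pytest.mark.parametrize("removed,expected", [
        (("bond", ("C", "S")), "C-S"),
        (("morse", ("Fe", "S")), "Fe-S"),
        (("angle", ("S", "S", "Fe")), "S-Fe-S"),
    ])
    def test_missing_parameter_names_interaction(self, toy_cluster, removed,
                                                 expected):
        structure, bonds = toy_cluster
        with pytest.raises(KeyError, match=expected):
            toy_cluster_calculator(structure, bonds, params={removed: None})


class TestEfeiWrap:
    def test_zero_force_is_identity(self, morse_calc, rng):
        wrapped = efei_wrap(morse_calc, (0, 1), 0.0)
        coords = np.array([[0.0, 0, 0], [0.1, -0.2, 2.4]])
        assert wrapped.energy(coords) == pytest.approx(morse_calc.energy(coords))
        np.testing.assert_allclose(wrapped.gradient(coords),
                                   morse_calc.gradient(coords), atol=1e-12)
        np.testing.assert_allclose(wrapped.hessian(coords),
                                   morse_calc.hessian(coords), atol=1e-8)

    def test_stationary_point_satisfies_closed_form(self, morse_calc,
                                                    diatomic_start):
        # 2 D_e β e^{-βx}(1-e^{-βx}) = F at the tilted-surface minimum
        force = 1.2
        res = optimize(efei_wrap(morse_calc, (0, 1), force), diatomic_start,
                       max_step=0.02)
        assert res.converged
        r = res.structure.distance(0, 1)
        beta = MORSE.beta_angstrom
        f_kj = 2 * MORSE.de * beta * np.exp(-beta * (r - MORSE.r0)) \
            * (1 - np.exp(-beta * (r - MORSE.r0)))
        assert f_kj / NN_TO_KJ_PER_MOL_PER_ANGSTROM == pytest.approx(force,
                                                                     abs=1e-3)

    def test_wrapped_gradient_matches_energy_fd(self, morse_calc, rng):
        wrapped = efei_wrap(morse_calc, (0, 1), 1.5)
        coords = np.array([[0.0, 0, 0], [0.3, 0.1, 2.5]])
        g = wrapped.gradient(coords)
        h = 1e-5
        flat = coords.reshape(-1)
        for col in range(6):
            xp, xm = flat.copy(), flat.copy()
            xp[col] += h
            xm[col] -= h
            fd = (wrapped.energy(xp.reshape(-1, 3))
                  - wrapped.energy(xm.reshape(-1, 3))) / (2 * h)
            assert g[col] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_coincident_pull_atoms_error(self, morse_calc):
        wrapped = efei_wrap(morse_calc, (0, 1), 1.0)
        with pytest.raises(ValueError, match="coincident"):
            wrapped.energy(np.zeros((2, 3)))

    def test_same_atom_pull_pair_rejected(self, morse_calc):
        with pytest.raises(ValueError):
            efei_wrap(morse_calc, (1, 1), 1.0)


class TestOptimize:
    def test_morse_diatomic_relaxes_to_equilibrium(self, morse_calc,
                                                   diatomic_start):
        res = optimize(morse_calc, diatomic_start)
        assert res.converged
        assert res.structure.distance(0, 1) == pytest.approx(2.300, abs=1e-3)

    def test_fully_frozen_returns_input_converged(self, diatomic_start):
        calc = harmonic_diatomic_calculator(2000.0, 1.0)
        res = optimize(calc, diatomic_start, frozen_atoms=[0, 1])
        assert res.converged and res.n_iterations == 0
        np.testing.assert_array_equal(res.structure.coords,
                                      diatomic_start.coords)

    def test_frozen_atoms_held_exactly(self, toy_cluster, toy_calc, rng):
        structure, _ = toy_cluster
        start = structure.with_coords(
            structure.coords + rng.normal(0, 0.05, (21, 3)))
        res = optimize(toy_calc, start, frozen_atoms=[0, 5])
        assert res.converged
        np.testing.assert_array_equal(res.structure.coords[[0, 5]],
                                      start.coords[[0, 5]])

    def test_perturbed_cluster_recovers_symmetric_minimum(self, toy_cluster,
                                                          toy_calc):
        structure, _ = toy_cluster
        rng = np.random.default_rng(99)
        start = structure.with_coords(
            structure.coords + rng.normal(0, 0.05, (21, 3)))
        res = optimize(toy_calc, start)
        assert res.converged
        fe_s = [res.structure.distance(0, k) for k in (1, 2, 3, 4)]
        np.testing.assert_allclose(fe_s, 2.3, atol=1e-3)

    def test_angle_constraint_held_under_load(self, toy_cluster, toy_calc):
        structure, _ = toy_cluster
        target = angle_value(structure.coords, 5, 1, 0)
        wrapped = efei_wrap(toy_calc, (5, 6), 1.5)
        res = optimize(wrapped, structure, max_step=0.02,
                       angle_constraints=[(5, 1, 0, target)])
        assert res.converged
        # residual deviation ~ generalized torque / k_restraint (~0.6 degrees
        # at 1.5 nN with the 1e4 kJ/mol/rad^2 restraint)
        held = angle_value(res.structure.coords, 5, 1, 0)
        assert abs(np.degrees(held - target)) < 1.0
        # and it shrinks with the load
        res_low = optimize(efei_wrap(toy_calc, (5, 6), 0.5), structure,
                           max_step=0.02, angle_constraints=[(5, 1, 0, target)])
        low_dev = abs(np.degrees(angle_value(res_low.structure.coords, 5, 1, 0)
                                 - target))
        assert low_dev < abs(np.degrees(held - target))


class TestFindRuptureForce:
    def test_morse_diatomic_matches_analytic_maximum(self, morse_calc,
                                                     diatomic_start):
        scan = find_rupture_force(morse_calc, diatomic_start, (0, 1), (0, 1),
                                  resolution=0.01)
        assert scan.rupture_force == pytest.approx(F_MAX_NN, abs=0.01)
        assert scan.bracket_high - scan.bracket_low <= 0.01 + 1e-12

    def test_harmonic_bond_never_ruptures(self):
        calc = harmonic_diatomic_calculator(2000.0, 1.0)
        start = AtomicStructure(("C", "C"), np.array([[0.0, 0, 0], [0, 0, 1.0]]))
        with pytest.raises(RuptureError, match="no rupture in range"):
            find_rupture_force(calc, start, (0, 1), (0, 1), force_cap=5.0)

    def test_force_balance_at_every_converged_trial(self, morse_calc,
                                                    diatomic_start):
        # applied and internal forces cancel at EFEI stationary points
        geom = diatomic_start
        for force in (0.5, 1.0, 1.8, 2.2):
            res = optimize(efei_wrap(morse_calc, (0, 1), force), geom,
                           max_step=0.02)
            assert res.converged
            geom = res.structure
            f_int = restoring_force(morse_calc, geom.coords, (0, 1))
            assert f_int == pytest.approx(force,
                                          abs=0.05 / NN_TO_KJ_PER_MOL_PER_ANGSTROM)

    def test_pull_pair_anisotropy_on_broken_symmetry(self):
        # staggered methyls + tilted sulfur directions: different carbon
        # pairs give different rupture forces (mechanical anisotropy)
        structure, bonds = build_toy_cluster(
            methyl_torsions_deg=(0.0, 25.0, 50.0, 75.0), s_fe_s_jitter_deg=4.0)
        calc = toy_cluster_calculator(structure, bonds)
        forces = {}
        for pair in ((5, 6), (5, 7)):
            scan = find_rupture_force(calc, structure, pair, (0, 1),
                                      resolution=0.02)
            forces[pair] = scan.rupture_force
        assert forces[(5, 6)] != forces[(5, 7)]
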