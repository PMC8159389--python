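import numpy as np
import pytest

from mechstrain.geom_io import AtomicStructure
from mechstrain.internal_coords import (
    InternalCoordinateSet,
    build_ric,
    delta_q,
    ric_values,
    wilson_b,
)
from mechstrain.jedi import hessian_to_internal, jedi_partition, strain_to_bonds

from conftest import random_rotation


def _random_spd_like(rng, n):
    """Random symmetric matrix (indefinite allowed)."""
    m = rng.normal(size=(n, n))
    return 0.5 * (m + m.T)


def _dummy_ric(n):
    """A coordinate set of n disjoint bonds, for partition-only tests."""
    return InternalCoordinateSet(
        tuple((2 * k, 2 * k + 1) for k in range(n)), (), (), np.zeros(n))


class TestHessianToInternal:
    def test_diatomic_recovers_force_constant(self):
        s = AtomicStructure(("H", "H"), np.array([[0.0, 0, 0], [0, 0, 0.74]]))
        ric = build_ric(s, [(0, 1)])
        B = wilson_b(s, ric)
        k = 575.0
        u = B[0]
        h_cart = k * np.outer(u, u)  # harmonic bond along the axis
        h_q = hessian_to_internal(h_cart, B)
        assert h_q.shape == (1, 1)
        assert h_q[0, 0] == pytest.approx(k, rel=1e-10)

    def test_zero_hessian_maps_to_zero(self, toy_cluster):
        structure, bonds = toy_cluster
        ric = build_ric(structure, bonds)
        B = wilson_b(structure, ric)
        h_q = hessian_to_internal(np.zeros((63, 63)), B)
        assert np.all(h_q == 0.0)

    def test_quadratic_form_equivalence(self, toy_cluster, toy_calc, rng):
        # ½ Δqᵀ H_q Δq must agree with ½ δxᵀ H_x δx for small displacements
        structure, bonds = toy_cluster
        ric = build_ric(structure, bonds)
        B = wilson_b(structure, ric)
        h_cart = toy_calc.hessian(structure.coords)
        h_q = hessian_to_internal(h_cart, B)
        for _ in range(5):
            dx = rng.normal(size=63)
            dx *= 1e-3 / np.linalg.norm(dx)
            cart = 0.5 * dx @ h_cart @ dx
            dq = delta_q(
                ric_values(ric, structure.coords + dx.reshape(-1, 3)), ric)
            internal = 0.5 * dq @ h_q @ dq
            assert internal == pytest.approx(cart, rel=0.01)

    def test_incomplete_coordinate_set_rejected(self, toy_cluster, rng):
        structure, bonds = toy_cluster
        # bonds alone (20 rows) cannot span 57 internal degrees of freedom
        ric = build_ric(structure, bonds)
        bonds_only = InternalCoordinateSet(ric.bonds, (), (),
                                           ric.values[:len(ric.bonds)])
        B = wilson_b(structure, bonds_only)
        h = _random_spd_like(rng, 63)
        with pytest.raises(ValueError, match="incomplete coordinate set"):
            hessian_to_internal(h, B)

    def test_asymmetric_hessian_rejected(self):
        s = AtomicStructure(("H", "H"), np.array([[0.0, 0, 0], [0, 0, 0.74]]))
        ric = build_ric(s, [(0, 1)])
        B = wilson_b(s, ric)
        h = np.arange(36.0).reshape(6, 6)
        with pytest.raises(ValueError, match="symmetric"):
            hessian_to_internal(h, B)


class TestJediPartition:
    def test_zero_displacement_zero_strain(self, rng):
        h_q = _random_spd_like(rng, 6)
        rep = jedi_partition(np.zeros(6), h_q, _dummy_ric(6))
        assert rep.total == 0.0
        assert np.all(rep.energies == 0.0)

    def test_decoupled_diagonal_case(self):
        h_q = np.diag([100.0, 50.0])
        rep = jedi_partition(np.array([0.2, 0.0]), h_q, _dummy_ric(2))
        assert rep.energies[0] == pytest.approx(0.5 * 100.0 * 0.04)
        assert rep.energies[1] == 0.0
        np.testing.assert_allclose(rep.percents, [100.0, 0.0])

    def test_conservation_random_forms(self, rng):
        # row-share attribution sums exactly to the quadratic form
        for _ in range(200):
            n = int(rng.integers(2, 30))
            h_q = _random_spd_like(rng, n)
            dq = rng.normal(size=n)
            rep = jedi_partition(dq, h_q, _dummy_ric(n))
            ref = 0.5 * dq @ h_q @ dq
            assert rep.total == pytest.approx(ref, rel=1e-12, abs=1e-12)
            if rep.total > 0:
                assert rep.percents.sum() == pytest.approx(100.0, abs=1e-6)

    def test_non_positive_total_flagged(self):
        h_q = np.diag([-10.0])
        rep = jedi_partition(np.array([0.5]), h_q, _dummy_ric(1))
        assert rep.non_positive
        assert rep.percents is None

    def test_rotation_invariance_end_to_end(self, toy_cluster, toy_calc, rng):
        structure, bonds = toy_cluster
        ric = build_ric(structure, bonds)
        dx = rng.normal(0, 0.01, structure.coords.shape)
        strained = structure.coords + dx

        def analyze(relaxed_coords, strained_coords):
            s = structure.with_coords(relaxed_coords)
            r = ric_values(ric, s)
            B = wilson_b(s, r)
            h_q = hessian_to_internal(toy_calc.hessian(relaxed_coords), B)
            dq = delta_q(ric_values(r, strained_coords), r)
            return jedi_partition(dq, h_q, r)

        base = analyze(structure.coords, strained)
        R = random_rotation(rng)
        shift = np.array([5.0, -3.0, 1.0])
        rot = analyze(structure.coords @ R.T + shift, strained @ R.T + shift)
        np.testing.assert_allclose(rot.energies, base.energies, atol=1e-8)


class TestStrainToBonds:
    def test_single_bond_keeps_its_energy(self):
        ric = InternalCoordinateSet(((0, 1),), (), (), np.array([1.0]))
        rep = jedi_partition(np.array([0.1]), np.array([[800.0]]), ric)
        assert strain_to_bonds(rep)[(0, 1)] == pytest.approx(rep.total)

    def test_angle_split_between_legs(self):
        ric = InternalCoordinateSet(
            ((0, 1), (0, 2)), ((1, 0, 2),), (),
            np.array([0.96, 0.96, 1.82]))
        rep = jedi_partition(np.array([0.0, 0.0, 0.1]),
                             np.diag([0.0, 0.0, 600.0]), ric)
        bonds = strain_to_bonds(rep)
        assert bonds[(0, 1)] == pytest.approx(rep.total / 2)
        assert bonds[(0, 2)] == pytest.approx(rep.total / 2)

    def test_torsion_split_three_ways(self):
        ric = InternalCoordinateSet(
            ((0, 1), (1, 2), (2, 3)), (), ((0, 1, 2, 3),),
            np.array([1.5, 1.5, 1.5, 0.3]))
        rep = jedi_partition(np.array([0, 0, 0, 0.3]),
                             np.diag([0.0, 0, 0, 66.67]), ric)
        bonds = strain_to_bonds(rep)
        for key in ((0, 1), (1, 2), (2, 3)):
            assert bonds[key] == pytest.approx(rep.total / 3)

    def test_conserves_total_on_full_cluster(self, toy_cluster, toy_calc, rng):
        structure, bonds = toy_cluster
        ric = build_ric(structure, bonds)
        B = wilson_b(structure, ric)
        h_q = hessian_to_internal(toy_calc.hessian(structure.coords), B)
        dq = delta_q(
            ric_values(ric, structure.coords
                       + rng.normal(0, 0.01, structure.coords.shape)), ric)
        rep = jedi_partition(dq, h_q, ric)
        mapped = strain_to_bonds(rep)
        assert sum(mapped.values()) == pytest.approx(rep.total, rel=1e-10)
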