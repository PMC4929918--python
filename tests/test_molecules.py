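"""Receptor/ligand geometry, molecular energies, unit conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoadhere.mesh import MembraneParams, build_flat_patch
from nanoadhere.molecules import (
    BondParams,
    Carrier,
    ReceptorParams,
    bond_energy,
    bound_bond_energy,
    fibonacci_sphere,
    flexural_energy,
    quat_from_axis_angle,
    quat_mul,
    quat_rotate,
    quat_to_euler_zxz,
    receptor_count,
    receptor_tip,
)
from nanoadhere.units import UnitSystem


class TestUnits:
    def test_H0_conversion_matches_hand_value(self):
        u = UnitSystem(300.0)
        beta_H0 = u.joule_to_kBT(-7.98e-20)
        assert beta_H0 == pytest.approx(-7.98e-20 / (1.380649e-23 * 300.0))
        assert beta_H0 == pytest.approx(-19.27, abs=0.01)

    def test_flexural_rigidity_conversion(self):
        u = UnitSystem(300.0)
        kf = u.pN_nm_to_kBT(7000.0)
        assert kf == pytest.approx(7000e-21 / (1.380649e-23 * 300.0))
        assert kf == pytest.approx(1690.0, abs=1.0)

    def test_bond_spring_conversion(self):
        u = UnitSystem(300.0)
        assert u.N_per_m_to_kBT_per_nm2(1.0) == pytest.approx(241.4, abs=0.1)

    @given(st.floats(min_value=1e-22, max_value=1e-18))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_identity(self, e):
        u = UnitSystem(300.0)
        assert u.kBT_to_joule(u.joule_to_kBT(e)) == pytest.approx(e, rel=1e-12)
        assert u.kBT_per_nm2_to_N_per_m(
            u.N_per_m_to_kBT_per_nm2(e * 1e18)) == pytest.approx(e * 1e18,
                                                                 rel=1e-12)


class TestFlexuralEnergy:
    def test_unflexed_is_zero(self):
        assert flexural_energy(0.0, ReceptorParams()) == 0.0

    def test_direct_formula(self):
        p = ReceptorParams(kappa_f=200.0)
        assert flexural_energy(0.1, p) == pytest.approx(1.0)

    def test_table_value_at_small_angle(self):
        # 7000 pN nm at 300 K: H_f(0.05 rad) = kf * 0.05^2 / 2
        p = ReceptorParams()
        expected = 0.5 * (7000e-21 / (1.380649e-23 * 300.0)) * 0.05**2
        assert flexural_energy(0.05, p) == pytest.approx(expected, rel=1e-9)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            flexural_energy(-0.1, ReceptorParams())
        with pytest.raises(ValueError):
            flexural_energy(3.5, ReceptorParams())


class TestBondEnergy:
    def test_at_reaction_range_equals_H0(self):
        p = BondParams(H0=-19.27, kappa_b=241.4, d_star=1.0)
        assert bond_energy(1.0, p) == pytest.approx(-19.27)

    def test_beyond_range_is_zero(self):
        p = BondParams()
        assert bond_energy(p.d_star * 1.01, p) == 0.0

    def test_harmonic_branch_inside(self):
        p = BondParams(H0=-10.0, kappa_b=2.0, d_star=1.0)
        assert bond_energy(0.5, p) == pytest.approx(-10.0 + 0.5 * 2.0 * 0.25)
        assert bound_bond_energy(1.5, p) == pytest.approx(
            -10.0 + 0.5 * 2.0 * 0.25)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            BondParams(H0=1.0)
        with pytest.raises(ValueError):
            BondParams(d_star=-1.0)


class TestReceptorTip:
    def test_unflexed_points_along_normal(self):
        p = ReceptorParams(length=19.0)
        tip = receptor_tip([0.0, 0.0, 0.0], [0.0, 0.0, 1.0], 0.0, 0.0, p)
        assert tip == pytest.approx([0.0, 0.0, 19.0])

    def test_right_angle_lands_in_tangent_plane(self):
        p = ReceptorParams(length=19.0)
        tip = receptor_tip([1.0, 2.0, 3.0], [0.0, 0.0, 1.0], math.pi / 2,
                           0.7, p)
        assert tip[2] == pytest.approx(3.0, abs=1e-12)
        assert np.linalg.norm(tip - [1.0, 2.0, 3.0]) == pytest.approx(19.0)

    @given(st.floats(0.0, math.pi / 2), st.floats(0.0, 2 * math.pi))
    @settings(max_examples=100, deadline=None)
    def test_rigid_rod_length(self, theta, phi):
        p = ReceptorParams(length=19.0)
        n = np.array([0.3, -0.4, 0.866])
        n /= np.linalg.norm(n)
        tip = receptor_tip([5.0, 5.0, 0.0], n, theta, phi, p)
        assert np.linalg.norm(tip - [5.0, 5.0, 0.0]) == pytest.approx(
            19.0, rel=1e-12)


class TestCarrier:
    def test_ligand_radial_geometry(self):
        car = Carrier(center=[0.0, 0.0, 100.0], radius=50.0,
                      ligand_length=15.0, n_ligands=162)
        bases = car.ligand_bases()
        tips = car.ligand_tips()
        rb = np.linalg.norm(bases - car.center, axis=1)
        rt = np.linalg.norm(tips - car.center, axis=1)
        assert rb == pytest.approx(np.full(162, 50.0), rel=1e-12)
        assert rt == pytest.approx(np.full(162, 65.0), rel=1e-12)

    def test_fibonacci_lattice_is_deterministic_and_unit(self):
        a = fibonacci_sphere(162)
        b = fibonacci_sphere(162)
        assert np.array_equal(a, b)
        assert np.linalg.norm(a, axis=1) == pytest.approx(np.ones(162))

    def test_quaternion_rotation_consistency(self):
        q = quat_from_axis_angle([0.0, 0.0, 1.0], math.pi / 2)
        v = quat_rotate(q, np.array([1.0, 0.0, 0.0]))
        assert v == pytest.approx([0.0, 1.0, 0.0], abs=1e-12)
        q2 = quat_mul(q, q)
        v2 = quat_rotate(q2, np.array([1.0, 0.0, 0.0]))
        assert v2 == pytest.approx([-1.0, 0.0, 0.0], abs=1e-12)

    def test_euler_angles_recover_simple_rotation(self):
        q = quat_from_axis_angle([1.0, 0.0, 0.0], 0.4)
        phi, theta, psi = quat_to_euler_zxz(q)
        assert theta == pytest.approx(0.4, abs=1e-9)


class TestReceptorCount:
    def test_density_times_projected_area(self):
        # 2000 um^-2 on a 0.25 um^2 patch
        assert receptor_count(2000.0, 500.0**2) == 500
        assert receptor_count(2000.0, 250.0**2) == 125
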