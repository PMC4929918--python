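"""Multivalency statistics, entropy estimators and the K_a assembly."""

import math
from types import SimpleNamespace

import numpy as np
import pytest

from nanoadhere.avidity import (
    EntropyEstimates,
    InsufficientSamplingError,
    InterpKnot,
    association_constant,
    entropy_estimators,
    interpolate_Ka,
    log_combinatorial,
    multivalency_histogram,
    normalize_kd,
)
from nanoadhere.fixtures import ToyBinding
from nanoadhere.free_energy import PMFCurve


def _traj(n_b, delta_r=None, bound_mom=None, nc_mom=None, quats=None,
          cadence=10, cadence_slow=100):
    return SimpleNamespace(
        n_b=np.asarray(n_b),
        delta_r=np.asarray(delta_r if delta_r is not None else []),
        bound_moments=np.asarray(bound_mom if bound_mom is not None
                                 else np.zeros(6)),
        nc_moments=np.asarray(nc_mom if nc_mom is not None else np.zeros(6)),
        cadence=cadence,
        cadence_slow=cadence_slow,
        euler_angles=lambda: (np.zeros((2, 3)) if quats is None else quats),
    )


class TestMultivalencyHistogram:
    def test_constant_series(self):
        stats = multivalency_histogram(_traj(np.full(1000, 3)))
        assert stats.mode == 3
        assert stats.probabilities[3] == pytest.approx(1.0)

    def test_binomial_series_mean(self, rng):
        nb = rng.binomial(20, 0.3, size=20000)
        stats = multivalency_histogram(_traj(nb))
        se = math.sqrt(20 * 0.3 * 0.7 / 20000)
        assert abs(stats.mean - 6.0) < 2 * se + 0.05

    def test_bound_segment_masking(self):
        # DeltaR exceeds r* in the second half: those samples are dropped
        nb = np.concatenate([np.full(500, 5), np.full(500, 0)])
        dr = np.concatenate([np.full(50, 60.0), np.full(50, 150.0)])
        stats = multivalency_histogram(_traj(nb, delta_r=dr), r_star=100.0)
        assert stats.mode == 5
        assert stats.n_samples == 500

    def test_empty_bound_segment_raises(self):
        nb = np.full(100, 2)
        dr = np.full(10, 150.0)
        with pytest.raises(InsufficientSamplingError):
            multivalency_histogram(_traj(nb, delta_r=dr), r_star=100.0)


class TestEntropyEstimators:
    def test_isotropic_gaussian_walk_area(self, rng):
        s = 3.0
        xy = s * rng.standard_normal((200_000, 2))
        mom = np.array([len(xy), xy[:, 0].sum(), xy[:, 1].sum(),
                        (xy[:, 0] ** 2).sum(), (xy[:, 1] ** 2).sum(),
                        (xy[:, 0] * xy[:, 1]).sum()])
        est = entropy_estimators(_traj(np.ones(10), bound_mom=mom,
                                       nc_mom=mom),
                                 total_area=62500.0, n_receptors=125)
        assert est.A_R_b == pytest.approx(math.pi * s * s, rel=0.05)
        assert est.A_R_u == pytest.approx(500.0)

    def test_pinned_receptor_hits_area_floor(self):
        mom = np.array([1000.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        est = entropy_estimators(_traj(np.ones(10), bound_mom=mom,
                                       nc_mom=mom),
                                 total_area=62500.0, n_receptors=125)
        assert est.A_R_b == pytest.approx(math.pi * 1e-4)

    def test_frozen_orientation_gives_zero_rot_volume(self):
        mom = np.array([1000.0, 0.0, 0.0, 1e4, 1e4, 0.0])
        est = entropy_estimators(
            _traj(np.ones(10), bound_mom=mom, nc_mom=mom,
                  quats=np.zeros((50, 3))),
            total_area=62500.0, n_receptors=125)
        assert est.rot_volume == 0.0

    def test_too_few_samples_raise(self):
        mom = np.array([5.0, 0.0, 0.0, 1.0, 1.0, 0.0])
        with pytest.raises(InsufficientSamplingError):
            entropy_estimators(_traj(np.ones(10), bound_mom=mom, nc_mom=mom),
                               total_area=1.0, n_receptors=1)


class TestAssociationConstant:
    def test_combinatorial_small_counts(self):
        # 3 receptors choose 2, 2 ligands choose 2 -> 3 * 1
        assert math.exp(log_combinatorial(3, 2, 2)) == pytest.approx(3.0)

    def test_formula_limit_free_rotation_no_bonds(self):
        # W == 0, n_b = 0, full rotational freedom:
        # K_a = A_N_b * r* / (L_z (L_z - r*))
        dr = np.linspace(0.0, 80.0, 161)
        pmf = PMFCurve(dr=dr, W=np.zeros_like(dr), err=np.zeros_like(dr),
                       anchored=True)
        ent = EntropyEstimates(A_R_b=100.0, A_R_u=100.0, A_N_b=400.0,
                               rot_volume=8 * math.pi**2)
        res = association_constant(pmf, None, ent, N_ant=10, N_ab=5,
                                   L_z=500.0, r_star=80.0, n_b=0)
        expected = 400.0 * 80.0 / (500.0 * (500.0 - 80.0))
        assert res.Ka == pytest.approx(expected, rel=1e-9)

    def test_matches_configurational_integral_oracle(self):
        toy = ToyBinding(w0=8.0, r0=20.0, k_w=0.1, r_star=60.0, L_z=500.0,
                         A_N_b=400.0)
        r, W = toy.pmf_grid(4001)
        pmf = PMFCurve(dr=r, W=W, err=np.zeros_like(r), anchored=True)
        ent = EntropyEstimates(A_R_b=1.0, A_R_u=1.0, A_N_b=toy.A_N_b,
                               rot_volume=8 * math.pi**2)
        res = association_constant(pmf, None, ent, N_ant=1, N_ab=1,
                                   L_z=toy.L_z, r_star=toy.r_star, n_b=1)
        oracle = toy.ka_oracle(n_samples=400_000, seed=99)
        assert res.Ka == pytest.approx(oracle, rel=0.10)

    def test_deeper_bond_raises_avidity(self):
        # monotonicity of K_a in the well depth
        kas = []
        for w0 in (4.0, 8.0, 12.0):
            toy = ToyBinding(w0=w0)
            r, W = toy.pmf_grid()
            pmf = PMFCurve(dr=r, W=W, err=np.zeros_like(r), anchored=True)
            ent = EntropyEstimates(A_R_b=1.0, A_R_u=1.0, A_N_b=toy.A_N_b,
                                   rot_volume=8 * math.pi**2)
            kas.append(association_constant(
                pmf, None, ent, 1, 1, toy.L_z, toy.r_star, n_b=1).log_Ka)
        assert kas[0] < kas[1] < kas[2]

    def test_all_components_finite_at_production_scale(self):
        dr = np.linspace(0.0, 100.0, 201)
        W = -25.0 * np.exp(-((dr - 30.0) / 12.0) ** 2)
        pmf = PMFCurve(dr=dr, W=W, err=np.zeros_like(dr), anchored=True)
        ent = EntropyEstimates(A_R_b=30.0, A_R_u=62500.0 / 1000.0,
                               A_N_b=80.0, rot_volume=0.05)
        res = association_constant(pmf, None, ent, N_ant=1000, N_ab=162,
                                   L_z=500.0, r_star=100.0, n_b=10)
        assert math.isfinite(res.log_Ka)
        for v in res.components.values():
            assert math.isfinite(v)
        assert res.log_Ka == pytest.approx(sum(res.components.values()))

    def test_domain_errors(self):
        dr = np.linspace(0.0, 80.0, 81)
        pmf = PMFCurve(dr=dr, W=np.zeros_like(dr), err=np.zeros_like(dr),
                       anchored=True)
        ent = EntropyEstimates(A_R_b=1.0, A_R_u=1.0, A_N_b=1.0,
                               rot_volume=1.0)
        with pytest.raises(ValueError):
            association_constant(pmf, None, ent, N_ant=2, N_ab=5, L_z=500.0,
                                 r_star=60.0, n_b=3)
        unanchored = PMFCurve(dr=dr, W=np.zeros_like(dr),
                              err=np.zeros_like(dr), anchored=False)
        with pytest.raises(ValueError):
            association_constant(unanchored, None, ent, 5, 5, 500.0, 60.0,
                                 n_b=1)


class TestInterpolation:
    def test_endpoint_identity(self):
        knot = InterpKnot(n1=200.0, n2=500.0, log_Ka1=10.0, log_Ka2=14.0)
        assert interpolate_Ka(knot, 200.0) == pytest.approx(10.0)
        assert interpolate_Ka(knot, 500.0) == pytest.approx(14.0)

    def test_midpoint_is_geometric_mean(self):
        knot = InterpKnot(n1=1.0, n2=3.0, log_Ka1=math.log(10.0),
                          log_Ka2=math.log(1000.0))
        assert math.exp(interpolate_Ka(knot, 2.0)) == pytest.approx(100.0)

    def test_log_linearity_three_point_collinearity(self):
        knot = InterpKnot(n1=200.0, n2=4000.0, log_Ka1=3.0, log_Ka2=17.0)
        xs = (500.0, 1000.0, 2000.0)
        ys = [interpolate_Ka(knot, x) for x in xs]
        slope1 = (ys[1] - ys[0]) / (xs[1] - xs[0])
        slope2 = (ys[2] - ys[1]) / (xs[2] - xs[1])
        assert slope1 == pytest.approx(slope2, abs=1e-12)

    def test_extrapolation_gated(self):
        knot = InterpKnot(n1=200.0, n2=500.0, log_Ka1=1.0, log_Ka2=2.0)
        with pytest.raises(ValueError):
            interpolate_Ka(knot, 100.0)
        assert interpolate_Ka(knot, 100.0, extrapolate=True) < 1.0


class TestNormalizedKd:
    def _res(self, log_ka):
        from nanoadhere.avidity import AvidityResult

        return AvidityResult(log_Ka=log_ka)

    def test_self_ratio_is_one(self):
        r = self._res(12.0)
        log_ratio, ratio = normalize_kd(r, r)
        assert ratio == pytest.approx(1.0)
        assert log_ratio == pytest.approx(0.0)

    def test_doubled_kd(self):
        a = self._res(12.0 - math.log(2.0))  # K_d doubled vs reference
        ref = self._res(12.0)
        _, ratio = normalize_kd(a, ref)
        assert ratio == pytest.approx(2.0)

    def test_ratio_chain_consistency(self):
        a, b, c = self._res(10.0), self._res(12.0), self._res(15.0)
        lab, rab = normalize_kd(a, b)
        lbc, rbc = normalize_kd(b, c)
        lac, rac = normalize_kd(a, c)
        assert rab * rbc == pytest.approx(rac, rel=1e-12)
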