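"""Tissue-targeting predictions and model-vs-experiment statistics."""

import numpy as np
import pytest

from nanoadhere.pk import (
    DEFAULT_MOUSE_ORGANS,
    OrganContext,
    TargetingConfigError,
    bootstrap_r2,
    contexts_from_frame,
    eta_with_uncertainty,
    null_contexts,
    null_model_test,
    percent_idg,
)


def _contexts():
    return [
        OrganContext(organ="lung", Kp=1.0, K_EC=50.0, dK_EC=5.0),
        OrganContext(organ="heart", Kp=0.5, K_EC=2.0, dK_EC=0.2),
        OrganContext(organ="liver", Kp=4.0, K_EC=5.0, dK_EC=0.5, phi_M=0.03,
                     K_M=1.0),
        OrganContext(organ="spleen", Kp=6.0, K_EC=5.0, dK_EC=0.5, phi_M=0.03,
                     K_M=1.0),
    ]


class TestPercentIdg:
    def test_macrophage_term_off_when_phi_zero(self):
        c = OrganContext(organ="lung", phi_M=0.0, K_M=123.0)
        assert percent_idg(c, include_macrophages=True) == pytest.approx(
            percent_idg(c, include_macrophages=False))

    def test_eta_invariant_under_Lcap_Cout_rescaling(self, rng):
        ctxs = _contexts()
        base = eta_with_uncertainty(ctxs, L_cap=5000.0, C_out=1.0)
        for _ in range(5):
            L_cap = float(10 ** rng.uniform(2, 5))
            C_out = float(10 ** rng.uniform(-3, 3))
            res = eta_with_uncertainty(ctxs, L_cap=L_cap, C_out=C_out)
            assert res.eta == pytest.approx(base.eta, rel=1e-12)

    def test_kp_dominated_limit(self):
        # make Kp K_EC >> phi_EC K_EC L_b D term by shrinking phi_EC
        ctxs = [
            OrganContext(organ="lung", Kp=1e9, K_EC=50.0, phi_EC=1e-6),
            OrganContext(organ="heart", Kp=2e9, K_EC=3.0, phi_EC=1e-6),
            OrganContext(organ="kidney", Kp=5e8, K_EC=7.0, phi_EC=1e-6),
        ]
        res = eta_with_uncertainty(ctxs)
        kpk = np.array([c.Kp * c.K_EC for c in ctxs])
        expected = kpk / kpk[0]
        assert res.eta == pytest.approx(expected, rel=0.01)

    def test_missing_K_for_enabled_scenario(self):
        c = OrganContext(organ="liver", phi_M=0.03, K_M=float("nan"))
        with pytest.raises(TargetingConfigError):
            percent_idg(c, include_macrophages=True)


class TestEta:
    def test_lung_is_unity_by_construction(self):
        res = eta_with_uncertainty(_contexts())
        assert res.eta[res.organs.index("lung")] == pytest.approx(1.0)

    def test_zero_dK_means_zero_spread(self):
        ctxs = [OrganContext(organ="lung", K_EC=50.0, dK_EC=0.0),
                OrganContext(organ="heart", K_EC=3.0, dK_EC=0.0)]
        res = eta_with_uncertainty(ctxs)
        assert res.eta_lo == pytest.approx(res.eta)
        assert res.eta_hi == pytest.approx(res.eta)

    def test_identical_contexts_all_unity(self):
        ctxs = [OrganContext(organ="lung", K_EC=5.0),
                OrganContext(organ="heart", K_EC=5.0),
                OrganContext(organ="kidney", K_EC=5.0)]
        res = eta_with_uncertainty(ctxs)
        assert res.eta == pytest.approx(np.ones(3))

    def test_missing_lung_raises(self):
        with pytest.raises(TargetingConfigError):
            eta_with_uncertainty([OrganContext(organ="heart")])


class TestBootstrapR2:
    def test_identical_inputs_give_unity(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        res = bootstrap_r2(x, 0.0, x, 0.0, seed=1)
        assert res.r2_mean == pytest.approx(1.0)
        assert res.r2_std == pytest.approx(0.0, abs=1e-12)

    def test_constructed_null_gives_near_zero(self):
        # exactly zero sample correlation, point-mass draws (sd -> 0)
        model = np.array([1.0, 3.0, 5.0, 3.0, 1.0])
        exp = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = bootstrap_r2(model, 0.0, exp, 0.0, seed=2, n_draws=500)
        assert res.r2_mean == pytest.approx(0.0, abs=1e-12)

    def test_seed_determinism(self):
        m = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1.1, 1.9, 3.2, 3.8])
        a = bootstrap_r2(m, 0.2, e, 0.3, seed=7, n_draws=200)
        b = bootstrap_r2(m, 0.2, e, 0.3, seed=7, n_draws=200)
        assert a.r2_mean == b.r2_mean
        assert np.array_equal(a.per_set, b.per_set)

    def test_too_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_r2([1.0, 2.0], 0.1, [1.0, 2.0], 0.1)


class TestNullModelTest:
    def _stats(self, values):
        from nanoadhere.pk import StatsResult

        v = np.asarray(values, float)
        return StatsResult(r2_mean=v.mean(), r2_std=v.std(ddof=1),
                           per_set=v, n_sets=len(v), n_draws=100, seed=0)

    def test_identical_groups_max_p(self):
        s = self._stats([0.5, 0.5, 0.5, 0.5, 0.5])
        assert null_model_test(s, s) == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        a = self._stats([0.90, 0.901, 0.899, 0.9, 0.9005])
        b = self._stats([0.30, 0.301, 0.299, 0.3, 0.3005])
        assert null_model_test(a, b) < 1e-6

    def test_two_sided_symmetry(self):
        a = self._stats([0.8, 0.82, 0.78, 0.81, 0.79])
        b = self._stats([0.5, 0.52, 0.48, 0.51, 0.49])
        assert null_model_test(a, b) == pytest.approx(null_model_test(b, a))

    def test_insufficient_sets_rejected(self):
        a = self._stats([0.8, 0.82])
        bad = self._stats([0.5])
        bad.n_sets = 1
        with pytest.raises(ValueError):
            null_model_test(a, bad)


class TestOrganTable:
    def test_default_table_builds_contexts(self):
        ctxs = contexts_from_frame(DEFAULT_MOUSE_ORGANS, K_EC=1.0)
        assert {c.organ for c in ctxs} == {"lung", "heart", "kidney",
                                           "liver", "spleen"}
        lung = next(c for c in ctxs if c.organ == "lung")
        heart = next(c for c in ctxs if c.organ == "heart")
        assert lung.N_ant == 2000.0 and heart.N_ant == 50.0
        spleen = next(c for c in ctxs if c.organ == "spleen")
        assert spleen.phi_M == pytest.approx(0.03)
        assert all("provenance" not in c.provenance.get("table", "")
                   or c.provenance for c in ctxs)

    def test_null_model_is_kp_only(self):
        ctxs = contexts_from_frame(DEFAULT_MOUSE_ORGANS, K_EC=1.0)
        nulls = null_contexts(ctxs)
        assert all(c.K_EC == 1.0 and c.K_M == 0.0 for c in nulls)

    def test_missing_required_column_rejected(self):
        import pandas as pd

        with pytest.raises(TargetingConfigError):
            contexts_from_frame(pd.DataFrame({"organ": ["lung"]}))
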