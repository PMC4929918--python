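"""Umbrella bias, WHAM reconstruction, TI anchoring, r* detection."""

import numpy as np
import pytest

from nanoadhere import fixtures as fx
from nanoadhere.free_energy import (
    AnchoringError,
    CoverageError,
    PMFCurve,
    UmbrellaWindow,
    bias_energy,
    bootstrap_wham,
    default_k_bias,
    detect_r_star,
    make_bin_edges,
    plateau_anchor,
    pmf_well_depth,
    ti_anchor,
    wham,
)


class TestBias:
    def test_zero_at_window_centre(self):
        assert bias_energy(37.0, 37.0) == 0.0

    def test_default_spring_from_ladder_spacing(self):
        assert default_k_bias(2.0) == pytest.approx(0.5)

    def test_one_kBT_at_one_window_spacing(self):
        assert bias_energy(39.0, 37.0, default_k_bias(2.0)) == pytest.approx(1.0)


def _sample_windows(toy, ladder, n, rng, lo, hi):
    kb = default_k_bias()
    edges = make_bin_edges(lo, hi)
    return [UmbrellaWindow.from_samples(
        toy.sample_window(x0, kb, n, rng), x0, kb, edges)
        for x0 in ladder]


class TestWham:
    def test_harmonic_toy_recovered(self, rng):
        toy = fx.harmonic_toy(k=0.5)
        wins = _sample_windows(toy, np.arange(-14, 14.1, 2.0), 100_000, rng,
                               -18, 18)
        pmf = wham(wins)
        sel = np.abs(pmf.dr) <= 10.0
        dev = pmf.W - 0.25 * pmf.dr**2
        dev -= dev[sel].mean()
        assert np.abs(dev[sel]).max() < 0.2

    def test_single_flat_window_gives_flat_pmf(self, rng):
        toy = fx.ToyUmbrella(lambda x: np.zeros_like(x), 0.0, 20.0)
        kb = 0.0001  # essentially unbiased
        edges = make_bin_edges(0.0, 20.0)
        w = UmbrellaWindow.from_samples(
            toy.sample_window(10.0, kb, 200_000, rng), 10.0, kb, edges)
        pmf = wham([w])
        inner = (pmf.dr > 2) & (pmf.dr < 18)
        assert pmf.W[inner].max() - pmf.W[inner].min() < 0.15

    def test_gauge_invariance_of_anchored_pmf(self, rng):
        toy = fx.well_toy(depth=5.0)
        wins = _sample_windows(toy, np.arange(0, 44.1, 2.0), 30_000, rng,
                               -4, 50)
        raw = wham(wins)
        shifted = PMFCurve(dr=raw.dr, W=raw.W + 3.7, err=raw.err)
        a1 = ti_anchor(raw, wins)
        a2 = ti_anchor(shifted, wins)
        assert a1.W == pytest.approx(a2.W, abs=1e-9)

    def test_non_overlapping_windows_raise(self, rng):
        toy = fx.harmonic_toy(k=0.5)
        kb = 50.0  # very stiff: histograms cannot bridge 10 units
        edges = make_bin_edges(-18, 18, bins_per_window=40)
        wins = [UmbrellaWindow.from_samples(
            toy.sample_window(x0, kb, 5000, rng), x0, kb, edges)
            for x0 in (-10.0, 10.0)]
        with pytest.raises(CoverageError):
            wham(wins)


class TestAnchoring:
    def test_well_depth_recovered(self, rng):
        toy = fx.well_toy(depth=5.0, x0=10.0, width=3.0)
        wins = _sample_windows(toy, np.arange(0, 44.1, 2.0), 50_000, rng,
                               -4, 50)
        anchored = ti_anchor(wham(wins), wins)
        assert pmf_well_depth(anchored) == pytest.approx(-5.0, abs=0.3)
        tail = (anchored.dr > 30) & (anchored.dr < 44)  # inside coverage
        assert np.abs(anchored.W[tail]).max() < 0.3

    def test_flat_landscape_anchors_to_zero(self, rng):
        toy = fx.ToyUmbrella(lambda x: np.zeros_like(x), -2.0, 30.0)
        wins = _sample_windows(toy, np.arange(0, 28.1, 2.0), 50_000, rng,
                               -2, 30)
        anchored = ti_anchor(wham(wins), wins)
        assert np.abs(anchored.W).max() < 0.2

    def test_ti_and_plateau_offsets_agree(self, rng):
        toy = fx.well_toy(depth=5.0, x0=10.0, width=3.0)
        wins = _sample_windows(toy, np.arange(0, 44.1, 2.0), 50_000, rng,
                               -4, 50)
        raw = wham(wins)
        o_ti = ti_anchor(raw, wins).offset
        o_pl = plateau_anchor(raw, plateau_from=30.0).offset
        assert o_ti == pytest.approx(o_pl, abs=0.3)

    def test_bootstrap_errors_are_positive_and_small(self, rng):
        toy = fx.well_toy(depth=5.0)
        wins = _sample_windows(toy, np.arange(0, 44.1, 2.0), 20_000, rng,
                               -4, 50)
        pmf = bootstrap_wham(wins, n_boot=10, seed=5)
        assert (pmf.err >= 0).all()
        assert np.median(pmf.err) < 0.5


class TestRStar:
    def _curve(self, flat_from=60.0):
        dr = np.linspace(0.0, 100.0, 201)
        W = np.where(dr < flat_from, -4.0 * np.exp(-((dr - 30) / 10) ** 2)
                     - 0.6 * (dr < flat_from), 0.0)
        return PMFCurve(dr=dr, W=W, err=np.zeros_like(dr), anchored=True)

    def test_constructed_flat_tail(self):
        assert detect_r_star(self._curve(60.0), tol=0.5) == pytest.approx(
            60.0, abs=1.0)

    def test_identically_zero_returns_first_point(self):
        dr = np.linspace(0.0, 50.0, 51)
        pmf = PMFCurve(dr=dr, W=np.zeros_like(dr), err=np.zeros_like(dr),
                       anchored=True)
        assert detect_r_star(pmf, tol=0.5) == pytest.approx(0.0)

    def test_zero_tolerance_rejected(self):
        with pytest.raises(ValueError):
            detect_r_star(self._curve(), tol=0.0)

    def test_unanchored_pmf_rejected(self):
        dr = np.linspace(0.0, 50.0, 51)
        pmf = PMFCurve(dr=dr, W=np.zeros_like(dr), err=np.zeros_like(dr),
                       anchored=False)
        with pytest.raises(AnchoringError):
            detect_r_star(pmf, tol=0.5)

    def test_never_flattening_curve_uses_fallback_or_raises(self):
        dr = np.linspace(0.0, 50.0, 51)
        pmf = PMFCurve(dr=dr, W=-5.0 + 0.0 * dr, err=np.zeros_like(dr),
                       anchored=True)
        with pytest.raises(AnchoringError):
            detect_r_star(pmf, tol=0.5)
        assert detect_r_star(pmf, tol=0.5, fallback=100.0) == 100.0
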