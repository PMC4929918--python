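"""Umbrella sampling along DeltaR, WHAM reconstruction and TI anchoring.

The adhesion order parameter is DeltaR = |R_CM - R_NC|, with R_CM the
centre of mass of membrane vertices within 2 r_NC of the carrier.
Windows are biased by U_bias = k_bias (DeltaR - DeltaR0)^2 / 2 on a
ladder with spacing deltaR (default 2 nm) and spring k_bias =
2 kBT / deltaR^2, so the carrier samples a full window at 1 kBT of
thermal energy.

WHAM combines the biased histograms self-consistently; the potential of
mean force W(DeltaR) is then defined up to an additive constant, which is
fixed by thermodynamic integration of the mean restraint force so that
the unbound state (DeltaR beyond the decorrelation cutoff r*) has zero
free energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_DELTA_R = 2.0  # nm window ladder spacing


class CoverageError(ValueError):
    """Umbrella windows do not overlap; WHAM cannot bridge the gap."""


class AnchoringError(RuntimeError):
    pass


def default_k_bias(delta_r: float = DEFAULT_DELTA_R) -> float:
    """k_bias = 2 kBT / deltaR^2 (= 0.5 kBT/nm^2 for the 2 nm ladder)."""
    return 2.0 / (delta_r * delta_r)


def bias_energy(dr: float, dr0: float, k_bias: float | None = None) -> float:
    """Harmonic umbrella restraint, k_B T."""
    if k_bias is None:
        k_bias = default_k_bias()
    return 0.5 * k_bias * (dr - dr0) ** 2


@dataclass
class UmbrellaWindow:
    """Biased DeltaR histogram for one ladder point."""

    dr0: float
    k_bias: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_samples: int
    seed: int = 0
    mean_dr: float = np.nan

    @classmethod
    def from_samples(cls, samples, dr0, k_bias, bin_edges, seed=0):
        samples = np.asarray(samples, dtype=float)
        counts, _ = np.histogram(samples, bins=bin_edges)
        return cls(dr0=dr0, k_bias=k_bias, bin_edges=np.asarray(bin_edges),
                   counts=counts.astype(float), n_samples=len(samples),
                   seed=seed, mean_dr=float(samples.mean()))

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PMFCurve:
    """Potential of mean force W(DeltaR), k_B T."""

    dr: np.ndarray
    W: np.ndarray
    err: np.ndarray
    anchored: bool = False
    offset: float = 0.0
    r_star: float | None = None

    def interp(self, x) -> np.ndarray:
        return np.interp(x, self.dr, self.W)


def make_bin_edges(dr_min: float, dr_max: float,
                   delta_r: float = DEFAULT_DELTA_R,
                   bins_per_window: int = 10) -> np.ndarray:
    """Shared histogram grid, bin width deltaR / bins_per_window."""
    width = delta_r / bins_per_window
    n = int(np.ceil((dr_max - dr_min) / width))
    return dr_min + width * np.arange(n + 1)


# ----------------------------------------------------------------------
def wham(
    windows: list[UmbrellaWindow],
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> PMFCurve:
    """Self-consistent WHAM solution (unanchored).

    Iterates window free energies f_i until the maximum change is below
    ``tol`` (k_B T).  Raises CoverageError when consecutive windows share
    no populated bins.
    """
    if len(windows) < 1:
        raise ValueError("at least one window required")
    edges = windows[0].bin_edges
    for w in windows[1:]:
        if len(w.bin_edges) != len(edges) or not np.allclose(w.bin_edges, edges):
            raise ValueError("all windows must share one histogram grid")
    centers = windows[0].centers
    counts = np.array([w.counts for w in windows])        # (K, B)
    N = np.array([w.n_samples for w in windows], float)   # (K,)
    # overlap diagnostic on the ladder
    order = np.argsort([w.dr0 for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not ((counts[a] > 0) & (counts[b] > 0)).any():
            raise CoverageError(
                f"no histogram overlap between windows at DeltaR0 = "
                f"{windows[a].dr0} and {windows[b].dr0}")
    bias = np.array([
        0.5 * w.k_bias * (centers - w.dr0) ** 2 for w in windows
    ])                                                     # (K, B)
    boltz = np.exp(-bias)
    total = counts.sum(axis=0)                             # (B,)
    f = np.zeros(len(windows))
    for _ in range(max_iter):
        denom = (N[:, None] * np.exp(f)[:, None] * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(denom > 0, total / denom, 0.0)
        z = (boltz * P[None, :]).sum(axis=1)
        f_new = -np.log(np.maximum(z, 1e-300))
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    denom = (N[:, None] * np.exp(f)[:, None] * boltz).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(denom > 0, total / denom, 0.0)
    good = P > 0
    W = np.full_like(P, np.nan)
    W[good] = -np.log(P[good])
    W -= np.nanmin(W)
    err = np.full_like(W, np.nan)
    err[good] = 1.0 / np.sqrt(np.maximum(total[good], 1.0))
    return PMFCurve(dr=centers[good], W=W[good], err=err[good])


def bootstrap_wham(windows, n_boot: int = 20, seed: int = 0, **kw) -> PMFCurve:
    """WHAM point estimate with multinomial-bootstrap uncertainties."""
    base = wham(windows, **kw)
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_boot):
        resampled = []
        for w in windows:
            tot = int(w.counts.sum())
            p = w.counts / max(tot, 1)
            cnew = rng.multinomial(tot, p).astype(float)
            resampled.append(UmbrellaWindow(
                dr0=w.dr0, k_bias=w.k_bias, bin_edges=w.bin_edges,
                counts=cnew, n_samples=w.n_samples, mean_dr=w.mean_dr))
        try:
            c = wham(resampled, **kw)
            curves.append(np.interp(base.dr, c.dr, c.W))
        except CoverageError:
            continue
    if curves:
        spread = np.std(np.array(curves) - np.array(curves).mean(axis=1,
                                                               keepdims=True),
                        axis=0)
        base.err = spread
    return base


# ----------------------------------------------------------------------
def ti_profile(windows: list[UmbrellaWindow]):
    """Free energy along the ladder by integrating the mean restraint force.

    dF/dDeltaR0 = <dU_bias/dDeltaR0> = -k_bias (<DeltaR> - DeltaR0);
    integrated inward from the outermost (unbound) window, which is
    assigned zero free energy.
    """
    order = np.argsort([w.dr0 for w in windows])
    lam = np.array([windows[i].dr0 for i in order])
    force = np.array([
        -windows[i].k_bias * (windows[i].mean_dr - windows[i].dr0)
        for i in order
    ])
    if np.isnan(force).any():
        raise AnchoringError("windows lack mean DeltaR for TI")
    F = np.zeros_like(lam)
    for i in range(len(lam) - 2, -1, -1):
        F[i] = F[i + 1] - 0.5 * (force[i] + force[i + 1]) * (lam[i + 1] - lam[i])
    return lam, F


def ti_anchor(pmf: PMFCurve, windows: list[UmbrellaWindow]) -> PMFCurve:
    """Fix the PMF's additive constant from the TI ladder profile.

    The stiff-spring ladder free energy tracks W up to a constant; the
    single constant is the mean discrepancy over the ladder, which pins
    W to the TI profile whose outermost (unbound) point is zero.
    """
    lam, F = ti_profile(windows)
    inside = (lam >= pmf.dr[0]) & (lam <= pmf.dr[-1])
    if inside.sum() < 2:
        raise AnchoringError("TI ladder does not overlap the PMF support")
    c = float(np.mean(F[inside] - pmf.interp(lam[inside])))
    return PMFCurve(dr=pmf.dr.copy(), W=pmf.W + c, err=pmf.err.copy(),
                    anchored=True, offset=c, r_star=pmf.r_star)


def plateau_anchor(pmf: PMFCurve, plateau_from: float) -> PMFCurve:
    """Alternative anchoring: zero the mean of W over the unbound plateau."""
    tail = pmf.dr >= plateau_from
    if tail.sum() < 2:
        raise AnchoringError(
            f"no PMF support beyond {plateau_from} for plateau anchoring")
    c = -float(np.mean(pmf.W[tail]))
    return PMFCurve(dr=pmf.dr.copy(), W=pmf.W + c, err=pmf.err.copy(),
                    anchored=True, offset=c, r_star=pmf.r_star)


def detect_r_star(pmf: PMFCurve, tol: float = 0.5,
                  fallback: float | None = None) -> float:
    """Smallest DeltaR beyond which |W| stays below tol (k_B T).

    The cutoff r* marks where carrier and membrane-receptor conformations
    cease to overlap.  ``fallback`` (e.g. 100 nm) is returned when the
    curve never settles, if provided; otherwise an AnchoringError is
    raised.
    """
    if not pmf.anchored:
        raise AnchoringError("detect_r_star requires an anchored PMF")
    if tol <= 0:
        raise ValueError("tolerance must be positive (noisy PMFs never "
                         "satisfy |W| < 0 persistently)")
    flat = np.abs(pmf.W) < tol
    # last index where |W| >= tol; r* is the next grid point
    above = np.flatnonzero(~flat)
    if len(above) == 0:
        return float(pmf.dr[0])
    idx = above[-1] + 1
    if idx >= len(pmf.dr):
        if fallback is not None:
            return float(fallback)
        raise AnchoringError("PMF does not flatten within the sampled range")
    return float(pmf.dr[idx])


def pmf_well_depth(pmf: PMFCurve) -> float:
    """W_min of an anchored PMF (k_B T; negative for attractive wells)."""
    return float(np.min(pmf.W))


# ----------------------------------------------------------------------
# umbrella orchestration for explicit systems
# ----------------------------------------------------------------------
def sample_umbrella_windows(
    system,
    base_config,
    dr0_ladder,
    k_bias: float | None = None,
    bin_edges: np.ndarray | None = None,
):
    """Run one biased simulation per ladder point (sequential warm start).

    ``system`` is evolved in place window after window, mimicking the
    dragging protocol; returns the list of UmbrellaWindow histograms
    built from the DeltaR series recorded at ``cadence_slow``.
    """
    from dataclasses import replace

    from .engine import run_simulation

    if k_bias is None:
        k_bias = default_k_bias()
    lad = np.sort(np.asarray(dr0_ladder, dtype=float))[::-1]  # outside-in
    if bin_edges is None:
        bin_edges = make_bin_edges(max(lad.min() - 3 * DEFAULT_DELTA_R, 0.0),
                                   lad.max() + 3 * DEFAULT_DELTA_R)
    windows = []
    for i, dr0 in enumerate(lad):
        cfg = replace(base_config, k_bias=k_bias, dr0=float(dr0),
                      seed=(base_config.seed * 131 + 7 * i + 1) % (2**31 - 1))
        traj = run_simulation(system, cfg)
        keep = traj.delta_r[len(traj.delta_r) // 5:]
        windows.append(UmbrellaWindow.from_samples(
            keep, dr0=float(dr0), k_bias=k_bias, bin_edges=bin_edges,
            seed=cfg.seed))
    return windows
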