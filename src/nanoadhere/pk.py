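"""Organ-level tissue-targeting predictions from association constants.

The steady-state standardized uptake (%idg, percent injected dose per
gram) of a carrier perfused at concentration C_out through capillaries
with cell-free layer L_cap is modelled as

    %idg ~ {Kp K_EC C_out + phi_EC K_EC L_EC,b D_EC C_out} (L_cap/L_EC,b)
           + phi_M K_M L_M,b D_M C_out (L_cap/L_M,b),

with Kp the non-targeted partition coefficient (IgG-control carriers),
K_EC / K_M the association constants on endothelial cells / macrophages,
phi_X and D_X the cell volume fraction and diameter, and L_X,b the bound-
layer thickness (the PMF cutoff r*).  All predictions are reported as
eta = (%idg)_organ / (%idg)_lung, in which C_out and L_cap cancel.

The grouping above reproduces the dominant-term limit
eta ~ (Kp K_EC)_org / (Kp K_EC)_lung, which is the contract the model is
validated against; the absolute %idg scale is arbitrary.

Model-vs-experiment agreement is scored with a Gaussian bootstrap
Pearson r^2 (five sets of 2000 draws) and an unpaired t-test against the
null model in which %idg is proportional to Kp alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats


class TargetingConfigError(ValueError):
    pass


@dataclass
class OrganContext:
    """Per-organ parameters with provenance notes.

    Densities are per projected membrane area (um^-2); kappa in k_B T;
    Aex in percent; Kp dimensionless; phi volume fractions; D in um;
    L_b in nm; K values in internal (nm-based) association-constant
    units with 1-sigma uncertainty dK.
    """

    organ: str
    species: str = "mouse"
    N_ant: float = 2000.0
    kappa: float = 40.0
    Aex: float = 10.0
    Kp: float = 1.0
    phi_EC: float = 0.30
    phi_M: float = 0.0
    D_EC: float = 5.0
    D_M: float = 5.0
    L_EC_b: float = 100.0
    L_M_b: float = 100.0
    K_EC: float = 1.0
    dK_EC: float = 0.0
    K_M: float = 0.0
    dK_M: float = 0.0
    provenance: dict = field(default_factory=dict)


@dataclass
class TargetingResult:
    """eta per organ with the K_EC +- dK_EC spread."""

    organs: list
    eta: np.ndarray
    eta_lo: np.ndarray
    eta_hi: np.ndarray
    idg: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "organ": self.organs,
            "eta": self.eta,
            "eta_lo": self.eta_lo,
            "eta_hi": self.eta_hi,
            "pct_idg_arbitrary": self.idg,
        })


@dataclass
class StatsResult:
    """Bootstrap r^2 with per-set values (for the null-model t-test)."""

    r2_mean: float
    r2_std: float
    per_set: np.ndarray
    n_sets: int
    n_draws: int
    seed: int


# ----------------------------------------------------------------------
def percent_idg(
    ctx: OrganContext,
    L_cap: float = 5000.0,
    C_out: float = 1.0,
    include_macrophages: bool = False,
    K_EC_override: float | None = None,
) -> float:
    """Standardized uptake (arbitrary common scale across organs)."""
    K_EC = ctx.K_EC if K_EC_override is None else K_EC_override
    if K_EC is None or not math.isfinite(K_EC):
        raise TargetingConfigError(f"{ctx.organ}: K_EC missing or non-finite")
    d_ec_nm = ctx.D_EC * 1000.0
    ec_term = (ctx.Kp * K_EC * C_out
               + ctx.phi_EC * K_EC * ctx.L_EC_b * d_ec_nm * C_out)
    out = ec_term * (L_cap / ctx.L_EC_b)
    if include_macrophages:
        if ctx.phi_M > 0 and (ctx.K_M is None or not math.isfinite(ctx.K_M)):
            raise TargetingConfigError(
                f"{ctx.organ}: macrophage scenario enabled but K_M missing")
        d_m_nm = ctx.D_M * 1000.0
        out += (ctx.phi_M * ctx.K_M * ctx.L_M_b * d_m_nm * C_out
                * (L_cap / ctx.L_M_b))
    return float(out)


def eta_with_uncertainty(
    ctxs: list[OrganContext],
    L_cap: float = 5000.0,
    C_out: float = 1.0,
    include_macrophages: bool = False,
) -> TargetingResult:
    """eta per organ, spread from evaluating at K_EC -+ dK_EC.

    Normalization is the lung %idg at the central K_EC.
    """
    lungs = [c for c in ctxs if c.organ.lower() == "lung"]
    if not lungs:
        raise TargetingConfigError("no lung context: cannot normalize eta")
    lung_idg = percent_idg(lungs[0], L_cap, C_out, include_macrophages)
    organs, eta, lo, hi, idg = [], [], [], [], []
    for c in ctxs:
        central = percent_idg(c, L_cap, C_out, include_macrophages)
        minus = percent_idg(c, L_cap, C_out, include_macrophages,
                            K_EC_override=max(c.K_EC - c.dK_EC, 0.0))
        plus = percent_idg(c, L_cap, C_out, include_macrophages,
                           K_EC_override=c.K_EC + c.dK_EC)
        organs.append(c.organ)
        idg.append(central)
        eta.append(central / lung_idg)
        lo.append(min(minus, plus) / lung_idg)
        hi.append(max(minus, plus) / lung_idg)
    return TargetingResult(
        organs=organs, eta=np.array(eta), eta_lo=np.array(lo),
        eta_hi=np.array(hi), idg=np.array(idg))


# ----------------------------------------------------------------------
def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    sx = x.std()
    sy = y.std()
    if sx < 1e-300 or sy < 1e-300:
        return 0.0
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r * r


def bootstrap_r2(
    model_mean,
    model_sd,
    exp_mean,
    exp_sd,
    seed: int = 0,
    n_sets: int = 5,
    n_draws: int = 2000,
) -> StatsResult:
    """Gaussian-replicate Pearson r^2 between model and experiment.

    Per set, ``n_draws`` paired replicate vectors are drawn from
    N(mean, sd) per organ (sd = 0 collapses to a point mass); the r^2 of
    each draw is averaged within the set.  The overall mean pools every
    draw; the quoted std is taken across the set means.
    """
    model_mean = np.asarray(model_mean, float)
    exp_mean = np.asarray(exp_mean, float)
    model_sd = np.broadcast_to(np.asarray(model_sd, float), model_mean.shape)
    exp_sd = np.broadcast_to(np.asarray(exp_sd, float), exp_mean.shape)
    if len(model_mean) != len(exp_mean) or len(model_mean) < 3:
        raise ValueError("need paired arrays of length >= 3")
    rng = np.random.default_rng(seed)
    per_set = np.empty(n_sets)
    for s in range(n_sets):
        r2s = np.empty(n_draws)
        for d in range(n_draws):
            xm = model_mean + model_sd * rng.standard_normal(len(model_mean))
            xe = exp_mean + exp_sd * rng.standard_normal(len(exp_mean))
            r2s[d] = _pearson_r2(xm, xe)
        per_set[s] = r2s.mean()
    return StatsResult(
        r2_mean=float(per_set.mean()),
        r2_std=float(per_set.std(ddof=1)),
        per_set=per_set,
        n_sets=n_sets,
        n_draws=n_draws,
        seed=seed,
    )


def null_model_test(model_stats: StatsResult, null_stats: StatsResult) -> float:
    """Two-sided unpaired t-test on the per-set r^2 values."""
    if model_stats.n_sets < 2 or null_stats.n_sets < 2:
        raise ValueError("need at least 2 bootstrap sets per group")
    t, p = sstats.ttest_ind(model_stats.per_set, null_stats.per_set)
    if math.isnan(p):
        return 1.0  # identical zero-variance groups: no evidence either way
    return float(p)


def null_contexts(ctxs: list[OrganContext]) -> list[OrganContext]:
    """Null hypothesis: %idg proportional to Kp alone (K_EC identical
    across organs, macrophage capture off)."""
    return [replace(c, K_EC=1.0, dK_EC=0.0, K_M=0.0, dK_M=0.0) for c in ctxs]


# ----------------------------------------------------------------------
# shipped default organ table
# ----------------------------------------------------------------------
_USER = "user-must-supply: control-IgG biodistribution / figure data"

DEFAULT_MOUSE_ORGANS = pd.DataFrame([
    # organ, N_ant (um^-2), kappa (kBT), Aex (%), Kp, phi_EC, phi_M, provenance
    ("lung", 2000.0, 40.0, 10.0, 1.0, 0.30, 0.00,
     "N_ant: lung endothelium ~2000 um^-2 (radio-labelling); "
     "kappa/Aex: endothelial mechanotype 40-60 kBT, 10-30%; Kp: " + _USER),
    ("heart", 50.0, 40.0, 10.0, 1.0, 0.30, 0.00,
     "N_ant: heart ~50 um^-2 (radio-labelling); Kp: " + _USER),
    ("kidney", 500.0, 40.0, 10.0, 1.0, 0.30, 0.00,
     "N_ant placeholder (" + _USER + ")"),
    ("liver", 500.0, 40.0, 10.0, 1.0, 0.30, 0.03,
     "N_ant placeholder; phi_M = 3% (clearance organ); Kp: " + _USER),
    ("spleen", 500.0, 40.0, 10.0, 1.0, 0.30, 0.03,
     "N_ant placeholder; phi_M = 3% (clearance organ); Kp: " + _USER),
], columns=["organ", "N_ant", "kappa", "Aex", "Kp", "phi_EC", "phi_M",
            "provenance"])


def contexts_from_frame(df: pd.DataFrame, species: str = "mouse",
                        **overrides) -> list[OrganContext]:
    """Build OrganContext objects from a table (TSV-compatible)."""
    required = {"organ", "N_ant", "Kp", "phi_EC", "phi_M"}
    missing = required - set(df.columns)
    if missing:
        raise TargetingConfigError(f"organ table missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        kwargs = dict(
            organ=row["organ"], species=species,
            N_ant=float(row["N_ant"]), Kp=float(row["Kp"]),
            phi_EC=float(row["phi_EC"]), phi_M=float(row["phi_M"]),
        )
        for col in ("kappa", "Aex", "D_EC", "D_M", "L_EC_b", "L_M_b",
                    "K_EC", "dK_EC", "K_M", "dK_M"):
            if col in df.columns:
                kwargs[col] = float(row[col])
        if "provenance" in df.columns:
            kwargs["provenance"] = {"table": str(row["provenance"])}
        kwargs.update(overrides)
        out.append(OrganContext(**kwargs))
    return out
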