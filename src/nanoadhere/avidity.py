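"""Binding-avidity assembly: multivalency statistics, entropy estimators
and the absolute association constant.

The association constant of a carrier with N_ab ligands forming n_b
simultaneous bonds on a patch carrying N_ant receptors is assembled from
simulation observables as

    K_a = [N_ant! / ((N_ant - n_b)! n_b!)] * C(N_ab, n_b)
          * (dphi dtheta dpsi / 8 pi^2)
          * (A_R^b / A_R^u)^{n_b}
          * A_N^b / (L_z (L_z - r*)) * int_0^{r*} exp(-W(r)) dr,

with A_R^b the bound-receptor traversal area, A_R^u = A / N_ant the
per-receptor share of the membrane area, A_N^b the lateral traversal
area of the bound carrier, the rotational volume the product of the
Euler-angle standard deviations, and W the anchored potential of mean
force.  All factors are assembled in log space (log-gamma for the
combinatorial terms), so the result is overflow-free for thousands of
receptors.  K_a carries internal (nm-based) units; every downstream use
is through ratios, where the units cancel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .free_energy import PMFCurve


class InsufficientSamplingError(RuntimeError):
    pass


EIGHT_PI_SQ = 8.0 * math.pi**2


@dataclass
class MultivalencyStats:
    """Normalized P(n_b) with bootstrap uncertainties."""

    n_values: np.ndarray
    probabilities: np.ndarray
    errors: np.ndarray
    mode: int
    mean: float
    n_samples: int

    def __post_init__(self) -> None:
        s = self.probabilities.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"P(n_b) sums to {s}, not 1")


@dataclass
class EntropyEstimates:
    """Areas (nm^2) and rotational volume (rad^3) entering the avidity."""

    A_R_b: float
    A_R_u: float
    A_N_b: float
    rot_volume: float
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if self.rot_volume < 0 or self.rot_volume > EIGHT_PI_SQ:
            raise ValueError(f"rotational volume {self.rot_volume} outside "
                             f"[0, 8 pi^2]")


@dataclass
class AvidityResult:
    """log K_a and its components; K_d = 1/K_a."""

    log_Ka: float
    components: dict = field(default_factory=dict)
    n_b: int = 0

    @property
    def Ka(self) -> float:
        return math.exp(self.log_Ka)

    @property
    def Kd(self) -> float:
        return math.exp(-self.log_Ka)

    @property
    def log_Kd(self) -> float:
        return -self.log_Ka


@dataclass
class InterpKnot:
    """Bracketing receptor densities and their association constants."""

    n1: float
    n2: float
    log_Ka1: float
    log_Ka2: float

    def __post_init__(self) -> None:
        if not (self.n2 > self.n1 > 0):
            raise ValueError(f"need n2 > n1 > 0, got {self.n1}, {self.n2}")

    @property
    def F1(self) -> float:
        """Free energy, F = -ln K_a (k_B T)."""
        return -self.log_Ka1

    @property
    def F2(self) -> float:
        return -self.log_Ka2


# ----------------------------------------------------------------------
def multivalency_histogram(
    traj,
    r_star: float | None = None,
    n_blocks: int = 50,
    seed: int = 0,
) -> MultivalencyStats:
    """P(n_b) over the bound segment of a trajectory.

    When ``r_star`` is given, fast-cadence n_b samples are kept only
    where the co-recorded DeltaR series (slow cadence) is below r_star.
    Errors are block-bootstrap standard deviations.
    """
    nb = np.asarray(traj.n_b)
    if r_star is not None and len(traj.delta_r):
        factor = max(traj.cadence_slow // traj.cadence, 1)
        mask_slow = np.asarray(traj.delta_r) < r_star
        mask = np.repeat(mask_slow, factor)[: len(nb)]
        if len(mask) < len(nb):
            mask = np.concatenate([mask, np.full(len(nb) - len(mask),
                                                 mask_slow[-1])])
        nb = nb[mask]
    if len(nb) == 0:
        raise InsufficientSamplingError("no bound-state samples below r*")
    n_max = int(nb.max())
    values = np.arange(n_max + 1)
    counts = np.bincount(nb, minlength=n_max + 1).astype(float)
    p = counts / counts.sum()
    # block bootstrap
    rng = np.random.default_rng(seed)
    blocks = np.array_split(nb, min(n_blocks, max(len(nb) // 10, 1)))
    boot = []
    for _ in range(200):
        pick = rng.integers(0, len(blocks), len(blocks))
        sample = np.concatenate([blocks[i] for i in pick])
        boot.append(np.bincount(sample, minlength=n_max + 1) / len(sample))
    err = np.std(np.array(boot), axis=0)
    return MultivalencyStats(
        n_values=values, probabilities=p, errors=err,
        mode=int(values[np.argmax(p)]), mean=float(nb.mean()),
        n_samples=len(nb))


def _moment_ellipse_area(mom: np.ndarray, coverage: float, floor: float):
    """pi * coverage^2 * sqrt(det Sigma) from streaming moments."""
    n = mom[0]
    if n < 2:
        return None
    mx, my = mom[1] / n, mom[2] / n
    sxx = mom[3] / n - mx * mx
    syy = mom[4] / n - my * my
    sxy = mom[5] / n - mx * my
    det = sxx * syy - sxy * sxy
    if det <= floor**4:
        return float(math.pi * coverage**2 * floor**2)
    return float(math.pi * coverage**2 * math.sqrt(det))


def entropy_estimators(
    traj,
    total_area: float,
    n_receptors: int,
    coverage: float = 1.0,
    area_floor: float = 1e-2,
    min_samples: int = 100,
) -> EntropyEstimates:
    """Traversal areas and rotational volume from a bound trajectory.

    A_R^b and A_N^b are covariance-ellipse areas (pi * coverage^2 *
    sqrt(det Sigma)) of the bound-receptor tangent coordinates and the
    carrier's lateral position; the rotational volume is the product of
    the three Euler-angle standard deviations.
    """
    if traj.bound_moments[0] < min_samples:
        raise InsufficientSamplingError(
            f"only {int(traj.bound_moments[0])} bound-receptor samples; "
            f"need >= {min_samples}")
    a_rb = _moment_ellipse_area(traj.bound_moments, coverage, area_floor)
    a_nb = _moment_ellipse_area(traj.nc_moments, coverage, area_floor)
    if a_rb is None or a_nb is None:
        warnings.warn("rank-deficient traversal covariance; using area floor")
        a_rb = a_rb or math.pi * area_floor**2
        a_nb = a_nb or math.pi * area_floor**2
    euler = traj.euler_angles()
    rot = float(np.prod(np.std(euler, axis=0)))
    return EntropyEstimates(
        A_R_b=a_rb,
        A_R_u=total_area / max(n_receptors, 1),
        A_N_b=a_nb,
        rot_volume=min(rot, EIGHT_PI_SQ),
        coverage=coverage,
    )


# ----------------------------------------------------------------------
def log_combinatorial(N_ant: int, N_ab: int, n_b: int) -> float:
    """ln{ [N_ant!/((N_ant-n_b)! n_b!)] * C(N_ab, n_b) }."""
    if n_b < 0 or n_b > N_ant or n_b > N_ab:
        raise ValueError(
            f"n_b = {n_b} outside the combinatorial domain "
            f"(N_ant = {N_ant}, N_ab = {N_ab})")
    return float(
        gammaln(N_ant + 1) - gammaln(N_ant - n_b + 1) - gammaln(n_b + 1)
        + gammaln(N_ab + 1) - gammaln(N_ab - n_b + 1) - gammaln(n_b + 1)
    )


def pmf_boltzmann_integral(pmf: PMFCurve, r_star: float) -> float:
    """int_0^{r*} exp(-W(r)) dr by trapezoid on the PMF grid (nm)."""
    grid = pmf.dr[pmf.dr <= r_star]
    if len(grid) < 2:
        raise ValueError("PMF grid has fewer than 2 points below r*")
    w = pmf.W[: len(grid)]
    # extend to [0, grid[0]] treating W as flat (hard-wall region is
    # typically unsampled; the Boltzmann factor there is negligible when
    # W rises, and flat extension is conservative for toy inputs)
    integral = float(np.trapezoid(np.exp(-w), grid))
    return integral


def association_constant(
    pmf: PMFCurve,
    stats: MultivalencyStats | None,
    ent: EntropyEstimates,
    N_ant: int,
    N_ab: int,
    L_z: float,
    r_star: float,
    n_b: int | None = None,
    n_b_rule: str = "mode",
) -> AvidityResult:
    """Assemble K_a in log space from the PMF and entropy estimators.

    ``n_b`` defaults to the modal multivalency of ``stats`` (or the mean,
    rounded, with ``n_b_rule='mean'``).
    """
    if not pmf.anchored:
        raise ValueError("association constant requires an anchored PMF "
                         "(unbound state at zero free energy)")
    if n_b is None:
        if stats is None:
            raise ValueError("provide either stats or an explicit n_b")
        n_b = stats.mode if n_b_rule == "mode" else int(round(stats.mean))
    if not 0 < r_star < L_z:
        raise ValueError(f"need 0 < r* < L_z, got r* = {r_star}, L_z = {L_z}")
    comps = {
        "combinatorial": log_combinatorial(N_ant, N_ab, n_b),
        "rotational": math.log(ent.rot_volume / EIGHT_PI_SQ)
        if ent.rot_volume > 0 else -math.inf,
        "translational_receptor": n_b * math.log(ent.A_R_b / ent.A_R_u),
        "translational_nc": math.log(ent.A_N_b / (L_z * (L_z - r_star))),
        "enthalpic": math.log(pmf_boltzmann_integral(pmf, r_star)),
    }
    log_ka = sum(comps.values())
    if not math.isfinite(log_ka):
        raise FloatingPointError(f"non-finite log K_a: components {comps}")
    return AvidityResult(log_Ka=log_ka, components=comps, n_b=n_b)


def interpolate_Ka(knot: InterpKnot, n_star: float,
                   extrapolate: bool = False) -> float:
    """log K_a at an intermediate receptor density (linear free energy).

    K_a* = K_a1^{(n2-n*)/(n2-n1)} * K_a2^{(n*-n1)/(n2-n1)}; returns
    log K_a* (log space throughout).
    """
    if not extrapolate and not (knot.n1 <= n_star <= knot.n2):
        raise ValueError(
            f"density {n_star} outside [{knot.n1}, {knot.n2}]; pass "
            "extrapolate=True to override")
    t = (n_star - knot.n1) / (knot.n2 - knot.n1)
    return (1.0 - t) * knot.log_Ka1 + t * knot.log_Ka2


def normalize_kd(result: AvidityResult, reference: AvidityResult):
    """K_d / K_d^dagger in log and linear form."""
    log_ratio = reference.log_Ka - result.log_Ka
    return log_ratio, math.exp(log_ratio)
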