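"""Metropolis Monte Carlo engine.

Seven elementary moves evolve the NC-membrane system: vertex move, link
flip, NC translation, NC rotation, receptor diffusion, receptor flexure
(Rosenbluth) and bond make/break (configurational bias).  One MC step is
one attempted elementary move.  By default half the attempts go to the
canonical moves (1-5, equally) and the other half is split between
flexure and bond moves in the ratio 2 : 5.

Step sizes for the displacement moves are auto-tuned during burn-in to a
30-50% acceptance window and then frozen (continued tuning would break
detailed balance).  All randomness flows from a single integer seed;
production runs are split into chunks with deterministically derived
sub-seeds, which is also the checkpoint/restart granularity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

logger = logging.getLogger(__name__)

from . import _kernels
from .molecules import quat_to_euler_zxz
from .system import AdhesionSystem, StateCorruptionError

DEFAULT_WEIGHTS = (0.1, 0.1, 0.1, 0.1, 0.1, 0.5 * 2 / 7, 0.5 * 5 / 7)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MoveMix:
    """Proposal probabilities for the seven move kinds (must sum to 1)."""

    weights: tuple = DEFAULT_WEIGHTS

    def __post_init__(self) -> None:
        if len(self.weights) != 7:
            raise ValueError("exactly seven move weights required")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"move weights sum to {sum(self.weights)}, not 1")

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(np.asarray(self.weights, dtype=np.float64))

    @classmethod
    def membrane_only(cls) -> "MoveMix":
        return cls((0.5, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0))


@dataclass
class SimulationConfig:
    """Schedule, step sizes and recording cadences for one MC run."""

    n_steps: int = 1_000_000
    seed: int = 0
    burn_in: int = 0
    move_mix: MoveMix = field(default_factory=MoveMix)
    cadence: int = 10          # fast observables (n_b)
    cadence_slow: int = 200    # DeltaR, orientation, energy
    step_vertex: float = 2.0   # nm, cube side for vertex displacement
    step_translate: float = 4.0
    step_rotate: float = 0.3   # rad
    k_trials: int = 8
    tune: bool = True
    k_bias: float = -1.0       # <= 0 disables the umbrella restraint
    dr0: float = 0.0
    n_chunks: int = 4
    checkpoint_path: str | None = None

    def __post_init__(self) -> None:
        if self.cadence < 1 or self.cadence_slow < 1:
            raise ValueError("recording cadences must be >= 1")
        if self.k_trials < 2:
            raise ValueError("Rosenbluth trial count must be >= 2")


@dataclass
class TrajectoryRecord:
    """Observable time series (units: nm, rad, k_B T)."""

    n_b: np.ndarray
    delta_r: np.ndarray
    quaternions: np.ndarray
    nc_center: np.ndarray
    energy: np.ndarray
    move_stats: np.ndarray       # (7, 2) attempts / accepts
    bound_moments: np.ndarray    # [n, Sx, Sy, Sxx, Syy, Sxy]
    nc_moments: np.ndarray
    cadence: int
    cadence_slow: int
    seed: int
    final_energy: float = 0.0
    final_delta_r: float = 0.0

    def euler_angles(self) -> np.ndarray:
        """(n, 3) ZXZ Euler angles (phi, theta, psi) of the NC."""
        out = np.empty((len(self.quaternions), 3))
        for i, q in enumerate(self.quaternions):
            out[i] = quat_to_euler_zxz(q)
        return out

    def acceptance_fractions(self) -> np.ndarray:
        att = np.maximum(self.move_stats[:, 0], 1)
        return self.move_stats[:, 1] / att


def metropolis_accept(delta_E: float, rng: np.random.Generator) -> bool:
    """Canonical acceptance: min(1, exp(-beta dE)); energies in k_B T."""
    if math.isnan(delta_E):
        raise SimulationError("NaN energy change")
    if delta_E <= 0.0:
        return True
    if math.isinf(delta_E):
        return False
    return bool(rng.random() < math.exp(-delta_E))


def flexural_solid_angle_norm(kappa_f: float) -> float:
    """Z = int over the upper hemisphere of exp(-kappa_f theta^2/2) dOmega."""
    val, _ = quad(lambda t: math.exp(-0.5 * kappa_f * t * t) * math.sin(t),
                  0.0, math.pi / 2.0, limit=200)
    return 2.0 * math.pi * val


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1000003 + 7919 * (k + 1) + 12345) % (2**31 - 1)


def _alloc_records(n_steps: int, cadence: int, cadence_slow: int):
    n_fast = (n_steps + cadence - 1) // cadence
    n_slow = (n_steps + cadence_slow - 1) // cadence_slow
    return (
        np.zeros(n_fast, np.int64),
        np.zeros(n_slow, np.float64),
        np.zeros((n_slow, 4), np.float64),
        np.zeros((n_slow, 3), np.float64),
        np.zeros(n_slow, np.float64),
    )


def _run_kernel(system: AdhesionSystem, config: SimulationConfig,
                n_steps: int, seed: int, z_norm: float, records, stats,
                bound_mom, nc_mom, step_sizes):
    ka = system.kernel_arrays()
    rec_nb, rec_dr, rec_quat, rec_center, rec_energy = records
    step_v, step_t, step_r = step_sizes
    energy, dr = _kernels.run_mc(
        ka["pos"], ka["nbr"], ka["nlink"], ka["deg"], ka["links"],
        ka["link_opp"], ka["link_tri"], ka["tris"], ka["pinned"],
        ka["rec_vertex"], ka["rec_theta"], ka["rec_phi"], ka["rec_bond"],
        ka["occupied"],
        ka["center"], ka["quat"], ka["lig_dirs"], ka["lig_tip"],
        ka["lig_bond"],
        ka["box"], ka["kappa"], ka["sigma"], ka["a0"], ka["lmax"],
        ka["rec_len"], ka["kappa_f"], ka["H0"], ka["kb"], ka["dstar"],
        ka["r_nc"], ka["lig_len"], ka["L_z"], z_norm,
        config.k_bias, config.dr0,
        config.move_mix.cumulative, step_v, step_t, step_r, config.k_trials,
        n_steps, seed,
        config.cadence, config.cadence_slow,
        rec_nb, rec_dr, rec_quat, rec_center, rec_energy,
        stats, bound_mom, nc_mom,
    )
    return energy, dr


def _tune_steps(system, config, z_norm, step_sizes, burn_in, seed):
    """Burn-in with acceptance-targeted step-size adaptation (then frozen)."""
    n_rounds = 8
    chunk = max(burn_in // n_rounds, 1)
    step_v, step_t, step_r = step_sizes
    for k in range(n_rounds):
        stats = np.zeros((7, 2), np.float64)
        bm = np.zeros(6)
        nm = np.zeros(6)
        records = _alloc_records(chunk, config.cadence, config.cadence_slow)
        _run_kernel(system, config, chunk, _sub_seed(seed, 1000 + k), z_norm,
                    records, stats, bm, nm, (step_v, step_t, step_r))
        for idx, name in ((0, "v"), (2, "t"), (3, "r")):
            if stats[idx, 0] < 10:
                continue
            acc = stats[idx, 1] / stats[idx, 0]
            fac = 1.0
            if acc < 0.30:
                fac = 1.0 / 1.35
            elif acc > 0.50:
                fac = 1.35
            if name == "v":
                step_v = min(max(step_v * fac, 0.01), 8.0)
            elif name == "t":
                step_t = min(max(step_t * fac, 0.01), 20.0)
            else:
                step_r = min(max(step_r * fac, 1e-3), 1.5)
        logger.info("burn-in round %d/%d: step sizes v=%.3f t=%.3f r=%.4f",
                    k + 1, n_rounds, step_v, step_t, step_r)
    logger.info("burn-in complete; step sizes frozen at v=%.3f t=%.3f r=%.4f",
                step_v, step_t, step_r)
    return step_v, step_t, step_r


def run_simulation(system: AdhesionSystem, config: SimulationConfig,
                   start_chunk: int = 0,
                   step_sizes: tuple | None = None) -> TrajectoryRecord:
    """Evolve the system in place and return the recorded trajectory.

    ``step_sizes`` overrides the (possibly burn-in-tuned) displacement
    magnitudes; checkpoint resumption passes the frozen values recorded
    at save time so the replayed tail is bit-identical.
    """
    z_norm = flexural_solid_angle_norm(system.receptors.kappa_f)
    frozen = step_sizes is not None
    if step_sizes is None:
        step_sizes = (config.step_vertex, config.step_translate,
                      config.step_rotate)
    if frozen:
        pass
    elif config.tune and config.burn_in > 0 and start_chunk == 0:
        step_sizes = _tune_steps(system, config, z_norm, step_sizes,
                                 config.burn_in, config.seed)
    elif config.burn_in > 0 and start_chunk == 0:
        records = _alloc_records(config.burn_in, config.cadence,
                                 config.cadence_slow)
        _run_kernel(system, config, config.burn_in,
                    _sub_seed(config.seed, 999), z_norm, records,
                    np.zeros((7, 2)), np.zeros(6), np.zeros(6), step_sizes)

    stats = np.zeros((7, 2), np.float64)
    bound_mom = np.zeros(6)
    nc_mom = np.zeros(6)
    chunk_len = config.n_steps // config.n_chunks
    pieces = []
    energy = dr = 0.0
    for k in range(start_chunk, config.n_chunks):
        n_k = chunk_len if k < config.n_chunks - 1 else \
            config.n_steps - chunk_len * (config.n_chunks - 1)
        records = _alloc_records(n_k, config.cadence, config.cadence_slow)
        energy, dr = _run_kernel(system, config, n_k,
                                 _sub_seed(config.seed, k), z_norm, records,
                                 stats, bound_mom, nc_mom, step_sizes)
        pieces.append(records)
        if config.checkpoint_path is not None:
            from .io_formats import save_checkpoint
            save_checkpoint(system, config.checkpoint_path, chunk_index=k + 1,
                            seed=config.seed, step_sizes=step_sizes)
            logger.info("checkpoint written after chunk %d -> %s", k + 1,
                        config.checkpoint_path)
        system.validate_bonds()
        with np.errstate(divide="ignore", invalid="ignore"):
            acc = np.where(stats[:, 0] > 0, stats[:, 1] /
                           np.maximum(stats[:, 0], 1), 0.0)
        logger.info("chunk %d/%d done: acceptance per move %s", k + 1,
                    config.n_chunks, np.round(acc, 3).tolist())

    traj = TrajectoryRecord(
        n_b=np.concatenate([p[0] for p in pieces]),
        delta_r=np.concatenate([p[1] for p in pieces]),
        quaternions=np.concatenate([p[2] for p in pieces]),
        nc_center=np.concatenate([p[3] for p in pieces]),
        energy=np.concatenate([p[4] for p in pieces]),
        move_stats=stats,
        bound_moments=bound_mom,
        nc_moments=nc_mom,
        cadence=config.cadence,
        cadence_slow=config.cadence_slow,
        seed=config.seed,
        final_energy=energy,
        final_delta_r=dr,
    )
    # cached-energy consistency guard (bias term is part of the cache)
    check = system.total_energy()
    if config.k_bias > 0 and system.carrier is not None:
        check += 0.5 * config.k_bias * (system.delta_r() - config.dr0) ** 2
    if abs(check - energy) > 1e-6 * max(1.0, abs(check)):
        raise StateCorruptionError(
            f"energy cache drift: recomputed {check}, cached {energy}")
    return traj


# ----------------------------------------------------------------------
# Python reference proposals (slow; used by unit tests and debugging)
# ----------------------------------------------------------------------
def propose_move(kind: int, system: AdhesionSystem,
                 rng: np.random.Generator,
                 step: float = 2.0):
    """Propose one canonical move (kinds 1-5); returns (apply, undo, dE).

    ``apply()`` commits the candidate, ``undo()`` restores the original
    state; constraint violations are signalled by dE = +inf.
    Kind numbering follows the move scheme (1-based).
    """
    if kind not in (1, 2, 3, 4, 5):
        raise ValueError(f"propose_move handles canonical moves 1-5, got {kind}")
    m = system.mesh
    e0 = system.total_energy()

    if kind == 1:  # vertex move
        v = int(rng.integers(m.n_vertices))
        delta = step * (rng.random(3) - 0.5)
        old = m.positions[v].copy()

        def apply():
            m.positions[v] = old + delta

        def undo():
            m.positions[v] = old

        apply()
        ll = np.linalg.norm(
            system._min_image(m.positions[m.neighbors[v, :m.degree[v]]]
                              - m.positions[v]), axis=1)
        bad = (ll < system.membrane.l_min).any() or (ll > system.membrane.l_max).any()
        if not bad and system.carrier is not None:
            bad = not system.check_excluded_volume()
        if system.pinned[v]:
            bad = True
        dE = math.inf if bad else system.total_energy() - e0
        undo()
        return apply, undo, dE

    if kind == 2:  # link flip
        li = int(rng.integers(m.n_links))
        a, b = (int(x) for x in m.links[li])
        t1, t2 = (int(x) for x in m.link_tri[li])
        c, d = (int(x) for x in m.link_opp[li])
        if not _kernels._has_directed_edge(m.triangles, t1, a, b):
            t1, t2 = t2, t1
            c, d = d, c
        newlen = np.linalg.norm(system._min_image(m.positions[d] - m.positions[c]))
        already = d in m.neighbors[c, :m.degree[c]]
        bad = (
            c == d or already or m.degree[a] <= 3 or m.degree[b] <= 3
            or newlen < system.membrane.l_min or newlen > system.membrane.l_max
        )

        def apply():
            _kernels._do_flip(li, a, b, c, d, t1, t2, m.links, m.link_opp,
                              m.link_tri, m.triangles, m.neighbors,
                              m.vertex_links, m.degree)

        def undo():
            _kernels._do_flip(li, c, d, b, a, t2, t1, m.links, m.link_opp,
                              m.link_tri, m.triangles, m.neighbors,
                              m.vertex_links, m.degree)

        if bad:
            return apply, undo, math.inf
        apply()
        dE = system.total_energy() - e0
        undo()
        return apply, undo, dE

    car = system.carrier
    if car is None:
        raise ValueError("moves 3-5 require a carrier / receptors")

    if kind == 3:  # NC translation
        delta = step * (rng.random(3) - 0.5)
        old = car.center.copy()

        def apply():
            car.center = old + delta

        def undo():
            car.center = old

        apply()
        bad = (not system.check_excluded_volume()
               or car.center[2] < car.radius
               or car.center[2] > system.box_height - car.radius)
        dE = math.inf if bad else system.total_energy() - e0
        undo()
        return apply, undo, dE

    if kind == 4:  # NC rotation
        from .molecules import quat_from_axis_angle, quat_mul

        axis = rng.standard_normal(3)
        ang = step * (rng.random() - 0.5)
        dq = quat_from_axis_angle(axis, ang)
        old = car.quaternion.copy()
        new = quat_mul(dq, old)
        new /= np.linalg.norm(new)

        def apply():
            car.quaternion = new

        def undo():
            car.quaternion = old

        apply()
        dE = system.total_energy() - e0
        undo()
        return apply, undo, dE

    # kind == 5: receptor hop
    r = int(rng.integers(system.n_receptors))
    v = int(system.rec_vertex[r])
    vnew = int(m.neighbors[v, rng.integers(m.degree[v])])

    def apply():
        system.occupied[v] = -1
        system.occupied[vnew] = r
        system.rec_vertex[r] = vnew

    def undo():
        system.occupied[vnew] = -1
        system.occupied[v] = r
        system.rec_vertex[r] = v

    if system.occupied[vnew] >= 0:
        return apply, undo, math.inf
    apply()
    dE = system.total_energy() - e0
    undo()
    return apply, undo, dE


def rosenbluth_flexure(system: AdhesionSystem, r: int,
                       rng: np.random.Generator, k_trials: int = 8) -> bool:
    """One Rosenbluth flexure update of receptor ``r`` (reference path).

    Candidates are drawn uniformly on the upper-hemisphere solid angle;
    one is selected with probability proportional to its Boltzmann factor
    and accepted with the ratio of new/old Rosenbluth weights.
    """
    if k_trials < 2:
        raise ValueError("k_trials must be >= 2")
    kf = system.receptors.kappa_f

    def energy_of(theta, phi):
        e = 0.5 * kf * theta * theta
        j = system.rec_bond[r]
        if j >= 0:
            old = (system.rec_theta[r], system.rec_phi[r])
            system.rec_theta[r], system.rec_phi[r] = theta, phi
            tip = system.receptor_tips()[r]
            system.rec_theta[r], system.rec_phi[r] = old
            lig = system.carrier.ligand_tips()[j]
            from .molecules import bound_bond_energy
            d = float(np.linalg.norm(system._min_image(tip - lig)))
            e += bound_bond_energy(d, system.bonds)
        return e

    cth = rng.random(k_trials)
    thetas = np.arccos(cth)
    phis = 2.0 * np.pi * rng.random(k_trials)
    e_cand = np.array([energy_of(t, p) for t, p in zip(thetas, phis)])
    w = np.exp(-e_cand)
    w_new = w.sum()
    if w_new <= 0:
        return False
    sel = int(rng.choice(k_trials, p=w / w_new))
    e_old = energy_of(system.rec_theta[r], system.rec_phi[r])
    th_o = np.arccos(rng.random(k_trials - 1))
    ph_o = 2.0 * np.pi * rng.random(k_trials - 1)
    w_old = math.exp(-e_old) + sum(
        math.exp(-energy_of(t, p)) for t, p in zip(th_o, ph_o))
    if rng.random() < w_new / w_old:
        system.rec_theta[r] = thetas[sel]
        system.rec_phi[r] = phis[sel]
        return True
    return False
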