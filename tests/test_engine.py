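"""MC engine: acceptance rule, move scheduling, detailed-balance oracles,
determinism and checkpointing."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from nanoadhere.engine import (
    MoveMix,
    SimulationConfig,
    SimulationError,
    metropolis_accept,
    propose_move,
    rosenbluth_flexure,
    run_simulation,
)
from nanoadhere.mesh import MembraneParams, build_flat_patch
from nanoadhere.molecules import BondParams, Carrier, ReceptorParams
from nanoadhere.system import AdhesionSystem


def _nc_system(L=160.0, kappa=50.0, seed=1, n_rec=40, kf=1690.0,
               H0=-19.27, center_dz=0.5):
    m = build_flat_patch(L, 10.0)
    p = MembraneParams(kappa=kappa, sigma=0.0, L=L)
    car = Carrier(center=[L / 2, L / 2, 50.0 + 15.0 + 19.0 + center_dz],
                  radius=50.0, ligand_length=15.0, n_ligands=162)
    return AdhesionSystem.place_receptors(
        m, p, n_rec, seed=seed, carrier=car,
        receptors=ReceptorParams(length=19.0, kappa_f=kf),
        bonds=BondParams(H0=H0, kappa_b=241.4, d_star=1.0),
        box_height=500.0)


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-5.0, rng) for _ in range(100))

    def test_infinite_barrier_always_rejected(self, rng):
        assert not any(metropolis_accept(math.inf, rng) for _ in range(100))

    def test_unit_barrier_rate_is_inverse_e(self, rng):
        n = 100_000
        acc = sum(metropolis_accept(1.0, rng) for _ in range(n)) / n
        p = math.exp(-1.0)
        assert abs(acc - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_nan_energy_is_hard_failure(self, rng):
        with pytest.raises(SimulationError):
            metropolis_accept(float("nan"), rng)


class TestMoveMix:
    def test_weights_validate(self):
        with pytest.raises(ValueError):
            MoveMix((0.5, 0.5, 0.0, 0.0, 0.0, 0.0, 0.1))

    def test_default_split_half_canonical_2_to_5(self):
        w = MoveMix().weights
        assert sum(w[:5]) == pytest.approx(0.5)
        assert w[5] / w[6] == pytest.approx(2.0 / 5.0)

    def test_scheduler_tallies_match_weights(self):
        system = _nc_system(n_rec=20)
        cfg = SimulationConfig(n_steps=300_000, seed=3, burn_in=0,
                               tune=False, n_chunks=1)
        traj = run_simulation(system, cfg)
        att = traj.move_stats[:, 0]
        frac = att / att.sum()
        for k, wk in enumerate(MoveMix().weights):
            se = math.sqrt(wk * (1 - wk) / att.sum())
            assert abs(frac[k] - wk) < 4 * se


class TestDeterminismAndInvariants:
    def test_same_seed_identical_trajectory(self):
        cfgs = [SimulationConfig(n_steps=120_000, seed=7, burn_in=10_000,
                                 n_chunks=2) for _ in range(2)]
        trajs = []
        for cfg in cfgs:
            system = _nc_system()
            trajs.append(run_simulation(system, cfg))
        assert np.array_equal(trajs[0].energy, trajs[1].energy)
        assert np.array_equal(trajs[0].n_b, trajs[1].n_b)

    def test_invariants_after_full_mixed_run(self):
        system = _nc_system()
        cfg = SimulationConfig(n_steps=400_000, seed=5, burn_in=40_000,
                               n_chunks=2)
        run_simulation(system, cfg)
        system.mesh.validate(system.membrane)      # Euler + link bounds
        system.validate_bonds()                    # partial matching
        assert system.check_excluded_volume()      # no vertex inside the NC

    def test_checkpoint_restores_bit_identical_tail(self, tmp_path):
        ck = tmp_path / "state.h5"
        cfg = SimulationConfig(n_steps=200_000, seed=9, burn_in=20_000,
                               n_chunks=2, checkpoint_path=str(ck))
        sys_a = _nc_system()
        run_simulation(sys_a, cfg)
        ref_pos = sys_a.mesh.positions.copy()
        ref_bonds = sys_a.rec_bond.copy()

        # replay: stop after chunk 1, reload, run chunk 2 only
        cfg_b = SimulationConfig(n_steps=200_000, seed=9, burn_in=20_000,
                                 n_chunks=2, checkpoint_path=str(tmp_path /
                                                                 "b.h5"))
        sys_b = _nc_system()
        # run only the first chunk by truncating, then resume
        from nanoadhere.io_formats import load_checkpoint, save_checkpoint

        cfg_first = SimulationConfig(n_steps=100_000, seed=9, burn_in=20_000,
                                     n_chunks=1,
                                     checkpoint_path=str(tmp_path / "b.h5"))
        run_simulation(sys_b, cfg_first)
        restored, meta = load_checkpoint(tmp_path / "b.h5")
        cfg_resume = SimulationConfig(n_steps=200_000, seed=9, burn_in=0,
                                      tune=False, n_chunks=2)
        run_simulation(restored, cfg_resume, start_chunk=1,
                       step_sizes=meta["step_sizes"])
        assert np.array_equal(restored.mesh.positions, ref_pos)
        assert np.array_equal(restored.rec_bond, ref_bonds)


class TestProposeMove:
    def test_link_flip_preserves_topology(self, flat_patch, flat_params, rng):
        system = AdhesionSystem(mesh=flat_patch, membrane=flat_params)
        flips = 0
        for _ in range(300):
            apply, undo, dE = propose_move(2, system, rng)
            if math.isfinite(dE) and metropolis_accept(dE, rng):
                apply()
                flips += 1
                assert flat_patch.euler_sum == 0
        assert flips > 10
        flat_patch.validate(flat_params)

    def test_nc_overlap_proposal_is_rejected(self, rng):
        system = _nc_system(center_dz=0.5)
        # force a translation straight down into the membrane
        car = system.carrier
        car.center[2] = car.radius + 0.5
        infs = 0
        for _ in range(50):
            _, _, dE = propose_move(3, system, rng, step=30.0)
            if math.isinf(dE):
                infs += 1
        assert infs > 0

    def test_receptor_hop_onto_occupied_vertex_rejected(self, rng):
        m = build_flat_patch(40.0, 10.0)
        p = MembraneParams(kappa=20.0, sigma=0.0, L=40.0)
        car = Carrier(center=[20.0, 20.0, 200.0], radius=50.0,
                      ligand_length=15.0, n_ligands=4)
        # receptors on every vertex except none free: all 16 occupied
        system = AdhesionSystem(
            mesh=m, membrane=p, carrier=car,
            rec_vertex=np.arange(16, dtype=np.int64),
            rec_theta=np.zeros(16), rec_phi=np.zeros(16),
            rec_bond=np.full(16, -1, np.int64))
        _, _, dE = propose_move(5, system, rng)
        assert math.isinf(dE)

    def test_unknown_kind_rejected(self, rng, flat_patch, flat_params):
        system = AdhesionSystem(mesh=flat_patch, membrane=flat_params)
        with pytest.raises(ValueError):
            propose_move(6, system, rng)


class TestEquilibriumOracles:
    def test_flexure_distribution_matches_quadrature(self, rng):
        kf = 5.0
        m = build_flat_patch(40.0, 10.0)
        p = MembraneParams(kappa=20.0, sigma=0.0, L=40.0)
        system = AdhesionSystem(
            mesh=m, membrane=p,
            receptors=ReceptorParams(length=19.0, kappa_f=kf),
            rec_vertex=np.array([0]), rec_theta=np.zeros(1),
            rec_phi=np.zeros(1), rec_bond=np.array([-1]),
            pinned=np.ones(m.n_vertices, bool))
        samples = []
        for i in range(30_000):
            rosenbluth_flexure(system, 0, rng, k_trials=8)
            if i >= 2000:
                samples.append(system.rec_theta[0])
        edges = np.linspace(0, np.pi / 2, 41)
        phat, _ = np.histogram(samples, bins=edges)
        phat = phat / phat.sum()
        Z = quad(lambda t: np.sin(t) * np.exp(-0.5 * kf * t * t), 0,
                 np.pi / 2)[0]
        pexp = np.array([quad(lambda t: np.sin(t) * np.exp(-0.5 * kf * t * t),
                              a, b)[0] / Z
                         for a, b in zip(edges[:-1], edges[1:])])
        assert np.abs(phat - pexp).max() < 0.02

    def test_stiff_rod_equipartition_limit(self, rng):
        kf = 200.0
        m = build_flat_patch(40.0, 10.0)
        p = MembraneParams(kappa=20.0, sigma=0.0, L=40.0)
        system = AdhesionSystem(
            mesh=m, membrane=p,
            receptors=ReceptorParams(length=19.0, kappa_f=kf),
            rec_vertex=np.array([0]), rec_theta=np.zeros(1),
            rec_phi=np.zeros(1), rec_bond=np.array([-1]),
            pinned=np.ones(m.n_vertices, bool))
        vals = []
        for i in range(120_000):
            rosenbluth_flexure(system, 0, rng, k_trials=8)
            if i >= 10_000:
                vals.append(system.rec_theta[0] ** 2)
        assert np.mean(vals) == pytest.approx(2.0 / kf, rel=0.05)

    def test_two_state_bond_occupancy_matches_partition_oracle(self):
        # clamped geometry: frozen flat membrane, single ligand on the
        # receptor's axis; only flexure + bond moves act
        L_an, L_ab, r_nc = 19.0, 15.0, 50.0
        d0, dstar, kf, H0, kb_ = 0.6, 1.0, 10.0, -3.0, 2.0
        m = build_flat_patch(80.0, 10.0)
        p = MembraneParams(kappa=20.0, sigma=0.0, L=80.0)
        car = Carrier(center=[0.0, 0.0, L_an + d0 + L_ab + r_nc],
                      radius=r_nc, ligand_length=L_ab,
                      ligand_dirs=np.array([[0.0, 0.0, -1.0]]))
        system = AdhesionSystem(
            mesh=m, membrane=p, carrier=car,
            receptors=ReceptorParams(length=L_an, kappa_f=kf),
            bonds=BondParams(H0=H0, kappa_b=kb_, d_star=dstar),
            rec_vertex=np.array([0]), rec_theta=np.zeros(1),
            rec_phi=np.zeros(1), rec_bond=np.array([-1]),
            pinned=np.ones(m.n_vertices, bool))
        cfg = SimulationConfig(
            n_steps=1_200_000, seed=9, burn_in=50_000, tune=False,
            move_mix=MoveMix((0, 0, 0, 0, 0, 0.3, 0.7)), n_chunks=1,
            cadence=10, cadence_slow=1000)
        traj = run_simulation(system, cfg)
        pb_mc = float((traj.n_b > 0).mean())

        ligtip = L_an + d0

        def d_of(th):
            return math.sqrt(L_an**2 + ligtip**2
                             - 2 * L_an * ligtip * math.cos(th))

        zu = quad(lambda th: math.exp(-0.5 * kf * th * th) * math.sin(th),
                  0, math.pi / 2)[0]
        zb = quad(lambda th: math.exp(
            -0.5 * kf * th * th
            - (H0 + 0.5 * kb_ * (d_of(th) - dstar) ** 2)) * math.sin(th),
            0, math.pi / 2)[0]
        pb_exact = zb / (zb + zu)
        nb = (traj.n_b > 0).astype(float)
        block = 2000
        bm = nb[: len(nb) // block * block].reshape(-1, block).mean(axis=1)
        se = bm.std(ddof=1) / math.sqrt(len(bm))
        assert abs(pb_mc - pb_exact) < 2.5 * se + 0.01

    def test_bond_limits(self):
        # ligand far beyond reach: bound fraction stays zero
        system = _nc_system(center_dz=40.0, n_rec=10)
        cfg = SimulationConfig(n_steps=100_000, seed=2, burn_in=0, tune=False,
                               n_chunks=1)
        traj = run_simulation(system, cfg)
        assert traj.n_b.max() == 0

    def test_ergodicity_two_seeds_agree(self):
        means = []
        for seed in (21, 87):
            system = _nc_system(L=160.0, kappa=50.0, seed=seed, n_rec=40,
                                center_dz=0.5 + 0.5 * (seed % 2))
            cfg = SimulationConfig(n_steps=2_500_000, seed=seed,
                                   burn_in=100_000, n_chunks=2)
            traj = run_simulation(system, cfg)
            half = traj.n_b[len(traj.n_b) // 2:]
            means.append(half.mean())
        assert abs(means[0] - means[1]) < 1.5
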