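"""Langevin integrator, thermostat physics, preparation and ensembles."""

import numpy as np
import pytest
from scipy import stats

from chainexpand import _kernels
from chainexpand.engine import (EnsembleConfig, equilibrate,
                                initialize_confined, initialize_free,
                                langevin_step, log_sample_times, release_run,
                                replica_seeds, run_ensemble)
from chainexpand.model import CavitySpec, ChainSnapshot, ModelParams
from chainexpand.observables import radius_of_gyration


def _single_bead(v=(0.0, 0.0, 0.0)):
    return ChainSnapshot(np.zeros((1, 3)), np.array([v], dtype=float))


class TestThermostat:
    def test_friction_only_decay_is_geometric(self, params, rng):
        # zero force, zero noise: v_k = v_0 exp(-eta dt/m * k) exactly
        snap = _single_bead((1.0, -2.0, 0.5))
        out = langevin_step(snap, params, rng, n_steps=10, noise=False)
        decay = np.exp(-params.eta * params.dt / params.mass * 10)
        assert np.allclose(out.velocities, snap.velocities * decay,
                           rtol=1e-12)

    def test_equipartition_and_normality(self, params, rng):
        # sample a single bead every 0.1 tu (>> m/eta = 0.05 tu memory)
        snap = _single_bead()
        samples = []
        for _ in range(2000):
            snap = langevin_step(snap, params, rng, n_steps=20)
            samples.append(snap.velocities[0].copy())
        v = np.array(samples).ravel()
        ke = 0.5 * params.mass * v ** 2
        se = ke.std(ddof=1) / np.sqrt(len(ke))
        assert abs(ke.mean() - 0.5 * params.kBT) < 3 * se
        assert stats.normaltest(v).pvalue > 1e-3

    def test_single_bead_diffusion_is_kT_over_eta(self, params, rng):
        # Einstein relation: <dr^2> = 6 D t with D = kBT/eta = 0.05
        T = 50.0
        n_steps = int(T / params.dt)
        disp2 = []
        for _ in range(120):
            snap = _single_bead(tuple(rng.normal(0, 1, 3)))
            out = langevin_step(snap, params, rng, n_steps=n_steps)
            disp2.append((out.positions[0] ** 2).sum())
        d_est = np.mean(disp2) / (6 * T)
        se = np.std(disp2, ddof=1) / np.sqrt(len(disp2)) / (6 * T)
        assert abs(d_est - 0.05) < 3 * se


class TestInitializeConfined:
    def test_containment_and_bonds(self, params, rng):
        snap = initialize_confined(32, 0.4, params, rng)
        wall = CavitySpec(32, 0.4).wall_radius
        assert np.all(np.linalg.norm(snap.positions, axis=1) <= wall + 1e-9)
        assert np.abs(snap.bond_lengths() - 1.0).max() < 0.05

    def test_loose_confinement(self, params, rng):
        snap = initialize_confined(64, 0.05, params, rng)
        wall = CavitySpec(64, 0.05).wall_radius
        assert np.all(np.linalg.norm(snap.positions, axis=1) <= wall + 1e-9)

    def test_no_residual_overlaps(self, params, rng):
        snap = initialize_confined(48, 0.4, params, rng)
        assert _kernels.min_nonbonded_distance(snap.positions) >= 0.8

    def test_seeds_give_distinct_states(self, params):
        a = initialize_confined(32, 0.4, params, np.random.default_rng(1))
        b = initialize_confined(32, 0.4, params, np.random.default_rng(2))
        assert not np.allclose(a.positions, b.positions)


class TestEquilibrate:
    def test_confined_rg_stationary(self, params):
        rng = np.random.default_rng(5)
        snap = initialize_confined(64, 0.4, params, rng)
        cav = CavitySpec(64, 0.4)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # no stationarity warning expected
            out, curve = equilibrate(snap, params, cav, 60_000, rng)
        # confined size close to the uniform-density sphere reference
        # Rg = sqrt(3/5) * D/2 (beads concentrate slightly below the wall,
        # so the measured value sits a little under the reference)
        ref = np.sqrt(3 / 5) * 0.5 * cav.D
        assert np.sqrt(curve.rg2[-20:].mean()) == pytest.approx(ref, rel=0.12)

    def test_free_chain_swells_beyond_confined_size(self, params):
        rng = np.random.default_rng(6)
        snap = initialize_confined(32, 0.4, params, rng)
        rg_confined = radius_of_gyration(snap.positions)
        out, curve = equilibrate(snap, params, None, 150_000, rng,
                                 check_stationarity=False)
        assert radius_of_gyration(out.positions) > 1.5 * rg_confined


class TestReleaseRun:
    def test_initial_rg_matches_snapshot(self, params):
        rng = np.random.default_rng(7)
        snap = initialize_confined(32, 0.4, params, rng)
        times = log_sample_times(100.0, n=40)
        size, shape, _ = release_run(snap, params, times, rng)
        assert size.rg2[0] == pytest.approx(
            radius_of_gyration(snap.positions) ** 2, rel=1e-12)

    def test_expansion_factor(self, params):
        rng = np.random.default_rng(8)
        snap = initialize_confined(32, 0.4, params, rng)
        snap, _ = equilibrate(snap, params, CavitySpec(32, 0.4), 40_000, rng,
                              check_stationarity=False)
        size, _, _ = release_run(snap, params, log_sample_times(2000.0, n=60),
                                 rng)
        assert np.sqrt(size.rg2[-1] / size.rg2[0]) > 1.5

    def test_deterministic_given_seed(self, params):
        def once():
            rng = np.random.default_rng(9)
            snap = initialize_confined(24, 0.3, params, rng)
            return release_run(snap, params, log_sample_times(50.0, n=20),
                               rng)[0]
        a, b = once(), once()
        assert np.array_equal(a.rg2, b.rg2)

    def test_eigenvalue_sum_matches_rg2_on_every_frame(self, params):
        rng = np.random.default_rng(10)
        snap = initialize_confined(32, 0.4, params, rng)
        size, shape, _ = release_run(snap, params,
                                     log_sample_times(200.0, n=50), rng)
        assert np.allclose(shape.eigvals.sum(axis=1), size.rg2, rtol=1e-10)

    def test_no_chain_crossing_distance(self, params):
        # minimum nonbonded distance stays above 0.8 sigma in production
        rng = np.random.default_rng(11)
        snap = initialize_confined(48, 0.4, params, rng)
        snap, _ = equilibrate(snap, params, CavitySpec(48, 0.4), 30_000, rng,
                              check_stationarity=False)
        assert _kernels.min_nonbonded_distance(snap.positions) > 0.8


class TestEnsembles:
    def test_replica_seeds_distinct_and_deterministic(self):
        s1 = replica_seeds(1234, 50)
        s2 = replica_seeds(1234, 50)
        assert np.array_equal(s1, s2)
        assert len(np.unique(s1)) == 50
        assert np.all(s1 >= 0) and np.all(s1 < 2 ** 31)

    def test_rerun_is_bit_identical(self, params):
        cfg = EnsembleConfig(N=16, phi0=0.3, replicas=2, seed=77,
                             params=params, equil_steps=5000,
                             sample_times=log_sample_times(20.0, n=10))
        a, b = run_ensemble(cfg), run_ensemble(cfg)
        assert np.array_equal(a.rg2, b.rg2)
        assert np.array_equal(a.eigvals, b.eigvals)
        assert np.array_equal(a.seeds, b.seeds)

    def test_standard_error_shrinks_with_replicas(self, params):
        cfg = EnsembleConfig(N=16, phi0=0.3, replicas=64, seed=88,
                             params=params, equil_steps=4000,
                             sample_times=np.array([0.0, 5.0, 10.0]))
        rec = run_ensemble(cfg)
        last = rec.rg2[:, -1]
        se_small = last[:16].std(ddof=1) / 4.0
        se_full = last.std(ddof=1) / 8.0
        # CLT: quadrupling replicas should halve the standard error
        assert se_full == pytest.approx(0.5 * se_small, rel=0.6)

    def test_free_chain_ensemble_runs(self, params):
        cfg = EnsembleConfig(N=24, phi0=None, replicas=3, seed=5,
                             params=params, free_relax_steps=2000,
                             sample_times=np.array([0.0, 5.0, 10.0]))
        rec = run_ensemble(cfg)
        assert rec.rg2.shape == (3, 3)
        assert rec.n_failed == 0


class TestInitializeFree:
    def test_self_avoiding(self, params, rng):
        snap = initialize_free(64, params, rng)
        assert _kernels.min_nonbonded_distance(snap.positions) >= 0.9 - 1e-12
        assert np.allclose(snap.bond_lengths(), 1.0, atol=1e-9)

    def test_velocity_variance(self, params):
        rng = np.random.default_rng(3)
        snaps = [initialize_free(16, params, rng) for _ in range(40)]
        v = np.concatenate([s.velocities.ravel() for s in snaps])
        assert v.var() == pytest.approx(params.kBT / params.mass, rel=0.1)
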