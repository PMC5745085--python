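"""SSA oracle and synthetic-data generator tests.

The heavier mean-field comparisons live in the acceptance suite; here the
kernel is pinned down on small networks with known exact behavior.
"""

import numpy as np
import pytest

from vgnodal import (
    ModelKind,
    StochasticConfig,
    default_observation_times,
    generate_noisy_trajectories,
    integrate,
    ssa_ensemble,
    ssa_run,
)
from vgnodal.model import AVOGADRO, M_PER_NM, S_PER_HPF
from vgnodal.stochastic import DEFAULT_OMEGA


@pytest.fixture(scope="module")
def record_times(params):
    return np.linspace(600.0, params.t_end, 30)


class TestSsaKernel:
    def test_pure_death_process_halves_at_half_life(self, params):
        # only Vg1 degradation active: binomial thinning of the initial pool
        p = params.replace(lambda_N_on=0.0, lambda_D=0.0, beta_N=0.0)
        t_half = np.log(2) / p.beta_V
        omega = 100 / (p.V0 * AVOGADRO)  # 100 nM -> 100 molecules
        cfg = StochasticConfig(
            record_times=np.array([t_half]), omega=omega, seed=3, n_replicates=400
        )
        survivors = [
            ssa_run(ModelKind.PRIMED_HETERODIMER, p, cfg, replicate=i).n_V[0]
            for i in range(cfg.n_replicates)
        ]
        # mean 50, SE = sqrt(100 * .5 * .5 / 400) = 0.25
        assert np.mean(survivors) == pytest.approx(50.0, abs=1.5)

    def test_single_pairing_waiting_time_is_exponential(self, params):
        # 1 N + 1 V with only dimerization active: the single event's
        # waiting time is Exp(rate = lambda_D/(Omega*NA)), so at one mean
        # waiting time the dimerized fraction is 1 - 1/e.
        omega = 1 / (1 * M_PER_NM * AVOGADRO)  # 1 nM <-> 1 molecule
        mean_wait = omega * AVOGADRO / params.lambda_D
        p = params.replace(
            lambda_N_on=0.0, beta_N=0.0, beta_V=0.0, V0=1 * M_PER_NM,
            t_on=1e7, t_off=2e7, t_end=3e7,
        )
        n_reps = 800
        cfg = StochasticConfig(
            record_times=np.array([mean_wait]), omega=omega, seed=11,
            n_replicates=n_reps,
        )
        dimerized = [
            ssa_run(
                ModelKind.PRIMED_HETERODIMER, p, cfg, replicate=i, n_N0=1
            ).n_D[0]
            for i in range(n_reps)
        ]
        expected = 1 - np.exp(-1)
        se = np.sqrt(expected * (1 - expected) / n_reps)
        assert np.mean(dimerized) == pytest.approx(expected, abs=4 * se)

    def test_no_nodal_means_inert_vg1_pool(self, params):
        # production off and N absent: a lone V molecule can only persist
        # (degradation also off), and no dimer can ever form
        omega = 1 / (1 * M_PER_NM * AVOGADRO)
        pv = params.replace(lambda_N_on=0.0, beta_N=0.0, beta_V=0.0, V0=1 * M_PER_NM)
        cfg0 = StochasticConfig(
            record_times=np.linspace(1, pv.t_end, 5), omega=omega, seed=1,
            n_replicates=1,
        )
        traj = ssa_run(ModelKind.PRIMED_HETERODIMER, pv, cfg0)
        assert np.all(traj.n_V == 1) and np.all(traj.n_N == 0)
        assert np.all(traj.n_D == 0)

    def test_all_zero_network_stays_zero(self, params):
        p = params.replace(lambda_N_on=0.0, V0=0.0)
        cfg = StochasticConfig(
            record_times=np.linspace(600, p.t_end, 10), seed=5, n_replicates=1
        )
        traj = ssa_run(ModelKind.COLD_START_HOMODIMER, p, cfg)
        assert not traj.n_N.any() and not traj.n_V.any() and not traj.n_D.any()

    def test_dimer_count_is_monotone(self, params, record_times):
        cfg = StochasticConfig(record_times=record_times, seed=9, n_replicates=3)
        for rep in range(3):
            for model in ModelKind:
                traj = ssa_run(model, params, cfg, replicate=rep)
                assert np.all(np.diff(traj.n_D) >= 0)
                assert (traj.n_N >= 0).all() and (traj.n_V >= 0).all()

    def test_primed_dimer_bounded_by_vg1_pool(self, params, record_times):
        cfg = StochasticConfig(record_times=record_times, seed=13, n_replicates=2)
        n_v0 = int(round(params.V0 * cfg.volume_factor))
        for rep in range(2):
            traj = ssa_run(ModelKind.PRIMED_HETERODIMER, params, cfg, replicate=rep)
            assert traj.n_D.max() <= n_v0

    def test_same_seed_reproduces_bitwise(self, params, record_times):
        cfg = StochasticConfig(record_times=record_times, seed=21, n_replicates=2)
        a = ssa_run(ModelKind.PRIMED_HETERODIMER, params, cfg, replicate=1)
        b = ssa_run(ModelKind.PRIMED_HETERODIMER, params, cfg, replicate=1)
        assert np.array_equal(a.n_N, b.n_N)
        assert np.array_equal(a.n_V, b.n_V)
        assert np.array_equal(a.n_D, b.n_D)

    def test_record_times_outside_horizon_rejected(self, params):
        cfg = StochasticConfig(
            record_times=np.array([params.t_end + 1.0]), seed=0, n_replicates=1
        )
        with pytest.raises(ValueError):
            ssa_run(ModelKind.PRIMED_HETERODIMER, params, cfg)


class TestEnsemble:
    def test_ensemble_matches_deterministic_mean_field(self, params):
        # small-but-meaningful ensemble; the full-size check is in acceptance
        rec = np.linspace(0.5, 10, 20) * S_PER_HPF
        cfg = StochasticConfig(record_times=rec, seed=17, n_replicates=100)
        summary = ssa_ensemble(ModelKind.COLD_START_HOMODIMER, params, cfg)
        grid = np.unique(np.concatenate([[0.0, params.t_on, params.t_off], rec]))
        det = integrate(ModelKind.COLD_START_HOMODIMER, params, grid=grid)
        d_det = np.interp(rec, det.times, det.D)
        within = np.abs(summary.mean["D"] - d_det) <= 3 * summary.se["D"] + 1e-30
        assert within.mean() >= 0.9

    def test_requires_two_replicates(self, params, record_times):
        cfg = StochasticConfig(record_times=record_times, seed=0, n_replicates=1)
        with pytest.raises(ValueError):
            ssa_ensemble(ModelKind.PRIMED_HETERODIMER, params, cfg)


class TestSyntheticDataset:
    def test_zero_noise_reproduces_deterministic_dimer(self, params):
        obs = default_observation_times(params)
        ds = generate_noisy_trajectories(params, 0.0, 3, obs, seed=1)
        traj = integrate(ModelKind.PRIMED_HETERODIMER, params)
        d = np.interp(obs, traj.times, traj.D)
        assert np.allclose(ds.observations, d[None, :], rtol=1e-9)

    def test_median_tracks_noiseless_curve(self, params):
        obs = np.arange(params.t_on + 1800.0, params.t_end, 1800.0)
        ds = generate_noisy_trajectories(params, 0.1, 50, obs, seed=2)
        traj = integrate(ModelKind.PRIMED_HETERODIMER, params)
        d = np.interp(obs, traj.times, traj.D)
        med = np.median(ds.observations, axis=0)
        assert np.all(np.abs(med - d) / d < 0.05)

    def test_determinism_and_positivity(self, params):
        obs = default_observation_times(params)
        a = generate_noisy_trajectories(params, 0.2, 5, obs, seed=42)
        b = generate_noisy_trajectories(params, 0.2, 5, obs, seed=42)
        assert np.array_equal(a.observations, b.observations)
        assert (a.observations > 0).all()

    def test_invalid_inputs_rejected(self, params):
        obs = default_observation_times(params)
        with pytest.raises(ValueError):
            generate_noisy_trajectories(params, -0.1, 5, obs, seed=0)
        with pytest.raises(ValueError):
            generate_noisy_trajectories(
                params, 0.1, 5, np.array([params.t_end + 1.0]), seed=0
            )
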