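"""Synthetic generators: determinism, ground-truth consistency, and the
statistical assumptions the estimators rely on."""

import numpy as np
import pytest

from neuroloop import synthetic
from neuroloop.preprocessing import TuningCurve8, update_direction_tuning
from neuroloop.synthetic import (
    ProtocolSpec,
    gen_behavior_neural_pair,
    gen_calcium_movie,
    gen_limit_cycle,
    gen_lnp_population,
    gen_photostim_network,
    gen_stim_protocol,
    gen_tuning_population,
    gen_tuning_surface,
    stimulus_onehot_series,
)


class TestProtocol:
    def test_counts_and_balance(self):
        events = gen_stim_protocol(ProtocolSpec(repetitions=3), seed=0)
        assert len(events) == 24
        angles = [e.angle_left for e in events]
        for d in range(0, 360, 45):
            assert angles.count(float(d)) == 3

    def test_moving_frames_at_default_rate(self):
        """4.2 s of motion at 3.6 Hz rounds to the 15-frame response window."""
        ev = gen_stim_protocol(ProtocolSpec(repetitions=1), seed=0)[0]
        assert ev.moving_frames == 15
        assert ev.stationary_frames == 19

    def test_seed_determinism(self):
        a = gen_stim_protocol(ProtocolSpec(), seed=5)
        b = gen_stim_protocol(ProtocolSpec(), seed=5)
        assert [e.angle_left for e in a] == [e.angle_left for e in b]

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            ProtocolSpec(moving_s=-1.0)


class TestCalciumMovie:
    def test_shape_and_determinism(self):
        movie, truth = gen_calcium_movie(5, 80, H=48, W=40, seed=1)
        assert movie.shape == (80, 48, 40)
        movie2, _ = gen_calcium_movie(5, 80, H=48, W=40, seed=1)
        np.testing.assert_array_equal(movie, movie2)

    def test_tuned_roi_peaks_at_preferred_direction(self):
        movie, truth = gen_calcium_movie(
            6, 700, noise_sd=0.0, seed=2,
            protocol=ProtocolSpec(repetitions=3),
        )
        i = 0
        pref = truth.preferred_directions[i]
        curve = TuningCurve8()
        for ev in truth.events:
            if ev.onset_frame + ev.moving_frames <= 700:
                curve = update_direction_tuning(
                    truth.fluorescence[i], ev, curve
                )
        best = np.argmax(curve.mean_response) * 45.0
        assert best == pref

    def test_too_many_rois_rejected(self):
        with pytest.raises(ValueError):
            gen_calcium_movie(1000, 10, H=32, W=32)


class TestTuningSurface:
    def test_argmax_is_stored_peak(self):
        for seed in range(10):
            truth = gen_tuning_surface(seed=seed)
            assert int(np.argmax(truth.surface)) == truth.peak

    def test_antipode_nearly_zero_for_narrow_widths(self):
        truth = gen_tuning_surface(seed=4, width_range=(2.0, 3.0))
        pi_, pj = truth.peak // 24, truth.peak % 24
        anti = truth.surface[(pi_ + 12) % 24, (pj + 12) % 24]
        assert anti < 0.05 * truth.amplitude

    def test_shared_peak_population(self):
        truths, oracle = gen_tuning_population(4, seed=0, shared_peak=100)
        assert all(t.peak == 100 for t in truths)
        resp = oracle(100)
        assert resp.shape == (4,)


class TestLNPPopulation:
    def test_baseline_rate_matches_poisson_mean(self):
        from neuroloop.models.lnp import lnp_init

        n, T = 4, 10_000
        params = lnp_init(n)
        params.b[:] = np.log(0.5)
        pop = gen_lnp_population(n, T, true_params=params,
                                 stim=np.zeros((T, 8)), seed=0)
        mean = pop.spikes.mean()
        se = np.sqrt(0.5 / (n * T))
        assert abs(mean - 0.5) < 3 * se

    def test_poisson_margin_variance_matches_mean(self):
        """Counts from the constant-rate model are Poisson: var ~ mean."""
        from neuroloop.models.lnp import lnp_init

        params = lnp_init(3)
        params.b[:] = np.log(0.8)
        pop = gen_lnp_population(3, 8000, true_params=params,
                                 stim=np.zeros((8000, 8)), seed=1)
        m, v = pop.spikes.mean(), pop.spikes.var()
        assert abs(v / m - 1.0) < 0.1

    def test_positive_coupling_gives_lagged_correlation(self):
        from neuroloop.models.lnp import lnp_init

        n = 2
        params = lnp_init(n)
        params.b[:] = np.log(0.5)
        params.W[1, 0] = 0.8  # neuron 0 drives neuron 1 at lag 1
        pop = gen_lnp_population(n, 6000, true_params=params,
                                 stim=np.zeros((6000, 8)), seed=2)
        s = pop.spikes
        x, y = s[:-1, 0], s[1:, 1]
        r = np.corrcoef(x, y)[0, 1]
        assert r > 0.1

    def test_unstable_coupling_rejected(self):
        from neuroloop.models.lnp import lnp_init

        params = lnp_init(3)
        params.W[:] = 1.0
        np.fill_diagonal(params.W, 0.0)
        with pytest.raises(ValueError, match="spectral radius"):
            gen_lnp_population(3, 100, true_params=params)

    def test_seed_determinism(self):
        a = gen_lnp_population(5, 200, seed=3)
        b = gen_lnp_population(5, 200, seed=3)
        np.testing.assert_array_equal(a.spikes, b.spikes)

    def test_stimulus_onehot_shape(self):
        events = gen_stim_protocol(ProtocolSpec(repetitions=1), seed=0)
        X = stimulus_onehot_series(events, 300)
        assert X.shape == (300, 8)
        assert set(np.unique(X)) <= {0.0, 1.0}
        assert np.all(X.sum(axis=1) <= 1)


class TestBehaviorNeuralPair:
    def test_noise_free_rank(self):
        frames, neural, truth = gen_behavior_neural_pair(
            rank=2, T=300, noise=0.0, seed=0
        )
        s = np.linalg.svd(frames.reshape(300, -1), compute_uv=False)
        assert s[1] > 1e-6 and s[2] < 1e-8

    def test_ridge_on_true_latents_recovers_map(self):
        from neuroloop.models.ridge import (
            ridge_coefficients, ridge_init, ridge_update,
        )

        frames, neural, truth = gen_behavior_neural_pair(
            rank=3, T=400, noise=0.0, seed=1
        )
        state = ridge_init(3, neural.shape[1], lam=1e-12)
        for t in range(400):
            ridge_update(state, truth.latents[t], neural[t])
        np.testing.assert_allclose(ridge_coefficients(state), truth.B, atol=1e-6)

    def test_rank_bound(self):
        with pytest.raises(ValueError):
            gen_behavior_neural_pair(H=4, W=4, rank=20, T=10)


class TestLimitCycle:
    def test_noise_free_is_planar(self):
        traj, truth = gen_limit_cycle(500, dims=5, noise_sd=0.0, seed=0)
        # residual outside the embedding plane vanishes
        proj = traj @ truth.basis @ truth.basis.T
        assert np.abs(traj - proj).max() < 1e-10

    def test_fft_period_matches_truth(self):
        traj, truth = gen_limit_cycle(1000, dims=2, noise_sd=0.0, period=100.0, seed=1)
        spec = np.abs(np.fft.rfft(traj[:, 0] - traj[:, 0].mean()))
        f = np.fft.rfftfreq(1000)
        period = 1.0 / f[np.argmax(spec[1:]) + 1]
        assert abs(period - truth.period) <= 1.0

    def test_seed_determinism(self):
        a, _ = gen_limit_cycle(100, seed=2)
        b, _ = gen_limit_cycle(100, seed=2)
        np.testing.assert_array_equal(a, b)

    def test_dims_bound(self):
        with pytest.raises(ValueError):
            gen_limit_cycle(100, dims=1)


class TestPhotostimNetwork:
    def test_single_coupling_targets_respond(self):
        coupling = np.zeros((4, 4))
        coupling[1, 3] = 1.5
        oracle, truth = gen_photostim_network(4, coupling=coupling, seed=0)
        resp = oracle(1)
        assert resp[3] == 1.5 and resp[[0, 1, 2]].sum() == 0

    def test_reproducible_under_seed(self):
        o1, t1 = gen_photostim_network(6, seed=5, noise_sd=0.1)
        o2, t2 = gen_photostim_network(6, seed=5, noise_sd=0.1)
        np.testing.assert_array_equal(o1(2), o2(2))
        np.testing.assert_array_equal(t1.coupling, t2.coupling)

    def test_invalid_coupling_rejected(self):
        bad = np.eye(3)  # nonzero diagonal
        with pytest.raises(ValueError):
            gen_photostim_network(3, coupling=bad)
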