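"""GP tuning estimation on the torus and the UCB/EI optimization loop."""

import numpy as np
import pytest
from scipy.stats import norm

from neuroloop.design.bo import (
    BOConfig,
    PopulationHistory,
    bo_loop,
    ei_stop,
    expected_improvement,
    optimize_population,
    peak_distance,
    ucb_select,
)
from neuroloop.design.gp import (
    GRID,
    GPKernel,
    N_POINTS,
    angle_to_index,
    gp_fit,
    grid_kernel_matrix,
)
from neuroloop.synthetic import gen_tuning_population, gen_tuning_surface


class TestGPFit:
    def test_no_observations_prior(self):
        post = gp_fit([], GPKernel(signal_var=2.0))
        np.testing.assert_array_equal(post.f, 0.0)
        np.testing.assert_allclose(post.sigma, np.sqrt(2.0))

    def test_near_interpolation_with_tiny_noise(self):
        kern = GPKernel(noise_var=1e-10)
        post = gp_fit([(100, 3.0)], kern)
        assert post.f.ravel()[100] == pytest.approx(3.0, abs=1e-4)
        assert post.sigma.ravel()[100] < 1e-4

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_dense_solve_oracle(self, seed):
        """Collapsed repeated-point solve equals the naive full system."""
        rng = np.random.default_rng(seed)
        kern = GPKernel(noise_var=0.05)
        pts = rng.integers(0, N_POINTS, 25)
        pts[:5] = pts[5:10]  # force repeats
        obs = [(int(p), float(rng.normal())) for p in pts]
        post = gp_fit(obs, kern)

        K = grid_kernel_matrix(kern)
        idx = np.array([p for p, _ in obs])
        y = np.array([v for _, v in obs])
        Kxx = K[np.ix_(idx, idx)] + kern.noise_var * np.eye(len(obs))
        alpha = np.linalg.solve(Kxx, y)
        test_pts = rng.integers(0, N_POINTS, 10)
        for p in test_pts:
            f_naive = K[p, idx] @ alpha
            var_naive = K[p, p] - K[p, idx] @ np.linalg.solve(Kxx, K[idx, p])
            assert post.f.ravel()[p] == pytest.approx(f_naive, abs=1e-8)
            assert post.sigma.ravel()[p] ** 2 == pytest.approx(
                var_naive, abs=1e-8
            )

    def test_sigma_shrinks_with_repeated_sampling(self):
        kern = GPKernel(noise_var=0.05)
        prev = np.sqrt(kern.signal_var)
        for n in (1, 3, 10, 30):
            post = gp_fit([(42, 1.0)] * n, kern)
            s = post.sigma.ravel()[42]
            assert s < prev
            prev = s

    def test_zero_noise_duplicates_raise(self):
        kern = GPKernel(noise_var=0.0)
        with pytest.raises(np.linalg.LinAlgError, match="noise"):
            gp_fit([(0, 1.0), (0, 2.0), (1, 0.5)], kern)


class TestUCB:
    def test_kappa_zero_is_greedy(self):
        post = gp_fit([(250, 5.0)], GPKernel(noise_var=1e-6))
        counts = np.zeros(N_POINTS, dtype=int)
        rng = np.random.default_rng(0)
        assert ucb_select(post, 0.0, counts, rng) == 250

    def test_fresh_prior_ties_to_index_zero(self):
        post = gp_fit([], GPKernel())
        counts = np.zeros(N_POINTS, dtype=int)
        assert ucb_select(post, 10.0, counts, np.random.default_rng(0)) == 0

    def test_repeat_cap_triggers_random_fallback(self):
        post = gp_fit([(250, 5.0)], GPKernel(noise_var=1e-6))
        counts = np.zeros(N_POINTS, dtype=int)
        counts[250] = 6  # sampled more than 5 times
        rng = np.random.default_rng(1337)
        expected = np.random.default_rng(1337).integers(N_POINTS)
        assert ucb_select(post, 0.0, counts, rng) == expected


class TestEI:
    def test_zero_sigma_stops(self):
        post = gp_fit([], GPKernel())
        post.sigma[:] = 0.0
        assert ei_stop(post, best_observed=0.0)

    def test_closed_form_at_best(self):
        """EI at a point with f = best and sd s equals s/sqrt(2*pi)."""
        post = gp_fit([], GPKernel())
        post.f[:] = 1.0
        post.sigma[:] = 0.3
        ei = expected_improvement(post, best_observed=1.0)
        np.testing.assert_allclose(ei, 0.3 * norm.pdf(0.0), atol=1e-12)
        assert 0.3 / np.sqrt(2 * np.pi) == pytest.approx(0.3 * norm.pdf(0.0))

    def test_large_uncertainty_keeps_going(self):
        post = gp_fit([], GPKernel(signal_var=4.0))
        assert not ei_stop(post, best_observed=0.0)


class TestPeakDistance:
    def test_zero_at_same_point(self):
        assert peak_distance((3, 7), (3, 7)) == 0.0

    def test_wraps_at_corners(self):
        assert peak_distance((0, 0), (23, 23)) == pytest.approx(np.sqrt(2))

    def test_antipodal_axis(self):
        assert peak_distance((0, 0), (12, 0)) == 12.0

    def test_linear_index_form(self):
        assert peak_distance(0, 23 * GRID + 23) == pytest.approx(np.sqrt(2))

    def test_metric_properties(self, rng):
        pts = [tuple(rng.integers(0, GRID, 2)) for _ in range(30)]
        for a, b, c in zip(pts, pts[1:], pts[2:]):
            assert peak_distance(a, b) == peak_distance(b, a)
            assert peak_distance(a, c) <= peak_distance(a, b) + peak_distance(b, c) + 1e-12


class TestBOLoop:
    def _noise_free_oracle(self, surface):
        flat = surface.ravel()
        return lambda p: np.array([flat[p]])

    def test_noise_free_finds_exact_argmax(self):
        for seed in range(5):
            truth = gen_tuning_surface(seed=seed, noise_sd=0.0)
            config = BOConfig(n_max=100)  # generous budget
            hist = PopulationHistory(1)
            post, peak, used = bo_loop(
                self._noise_free_oracle(truth.surface), config, hist, 0
            )
            assert peak == truth.peak, seed

    def test_flat_surface_stops_early(self):
        config = BOConfig()
        hist = PopulationHistory(1)
        post, peak, used = bo_loop(lambda p: np.zeros(1), config, hist, 0)
        assert used < config.n_max

    def test_stimulus_cap_respected(self):
        """Adversarial noise keeps EI high; the loop still stops at 30."""
        rng = np.random.default_rng(0)
        config = BOConfig()
        hist = PopulationHistory(1)
        post, peak, used = bo_loop(
            lambda p: rng.normal(0, 10.0, 1), config, hist, 0
        )
        assert used <= 30

    def test_initial_stimuli_are_whole_field_diagonal(self):
        config = BOConfig()
        stims = config.init_stimuli(np.random.default_rng(1337))
        assert len(stims) == 8
        for p in stims:
            assert p // GRID == p % GRID  # same angle in both eyes
            assert (p // GRID) % 3 == 0  # 45-degree spacing on a 15-deg grid


class TestPopulationSharing:
    def test_sharing_reduces_total_presentations(self):
        """Correlated neurons: the population presents far fewer distinct
        stimuli than (the first neuron's solo budget) x (neuron count)."""
        n = 10
        truths, oracle = gen_tuning_population(
            n, seed=3, noise_sd=0.2, shared_peak=5 * GRID + 5
        )
        # solo budget: optimize the first neuron with a fresh history
        _, solo_hist = optimize_population(lambda p: oracle(p)[:1], 1)
        solo_used = len(solo_hist.presented)
        _, hist = optimize_population(oracle, n)
        distinct = len(set(hist.presented))
        assert distinct < solo_used * n

    def test_every_neuron_gets_full_history(self):
        hist = PopulationHistory(3)
        hist.record(7, np.array([1.0, 2.0, 3.0]))
        assert [len(hist.observations[i]) for i in range(3)] == [1, 1, 1]
        assert hist.sample_counts[7] == 1

    def test_angle_index_roundtrip(self):
        assert angle_to_index(45.0, 45.0) == 3 * GRID + 3
        assert angle_to_index(345.0, 0.0) == 23 * GRID
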