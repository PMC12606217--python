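"""Linear-nonlinear-Poisson model: rates, likelihood, gradients, fitting."""

import numpy as np
import pytest

from neuroloop.models.lnp import (
    LNPFitter,
    LNPParams,
    LNPWindow,
    lnp_gradient,
    lnp_init,
    lnp_loglik,
    lnp_rate,
    lnp_sgd_step,
    top_connections,
)
from neuroloop.synthetic import gen_lnp_population, gen_random_lnp_params


def naive_loglik(params, S, X, w0):
    """Independent double-loop evaluation of the window log-likelihood."""
    T, n = S.shape
    total = 0.0
    for t in range(w0, T):
        for i in range(n):
            eta = params.b[i] + params.K[i] @ X[t]
            for lag in range(1, 5):
                if t - lag >= 0:
                    eta += params.H[i, lag - 1] * S[t - lag, i]
            if t - 1 >= 0:
                eta += params.W[i] @ S[t - 1]
            total += S[t, i] * eta - np.exp(min(eta, 30.0))
    return total


def filled_window(n, T, seed=0):
    pop = gen_lnp_population(n, T, seed=seed)
    w = LNPWindow(n, window=min(T, 100))
    for t in range(T):
        w.push(pop.spikes[t], pop.stim[t])
    return pop, w


class TestRate:
    def test_baseline_only(self):
        p = lnp_init(3)
        p.b[:] = np.log(0.5)
        rate = lnp_rate(p, np.zeros(8), np.zeros((3, 4)), np.zeros(3))
        np.testing.assert_allclose(rate, 0.5)

    def test_unit_stimulus_weight_gives_e(self):
        p = lnp_init(1)
        p.K[0, 3] = 1.0
        s = np.zeros(8); s[3] = 1.0
        rate = lnp_rate(p, s, np.zeros((1, 4)), np.zeros(1))
        assert rate[0] == pytest.approx(np.e)

    def test_coupling_only_matches_hand_computation(self, rng):
        n = 5
        p = lnp_init(n)
        p.W = rng.standard_normal((n, n)) * 0.3
        np.fill_diagonal(p.W, 0.0)
        y_prev = rng.poisson(1.0, n).astype(float)
        rate = lnp_rate(p, np.zeros(8), np.zeros((n, 4)), y_prev)
        np.testing.assert_allclose(rate, np.exp(p.W @ y_prev), atol=1e-12)

    def test_overflow_clipped(self):
        p = lnp_init(1)
        p.b[0] = 100.0
        rate = lnp_rate(p, np.zeros(8), np.zeros((1, 4)), np.zeros(1))
        assert rate[0] == pytest.approx(np.exp(30.0))


class TestLoglik:
    def test_zero_spikes_constant_rate(self):
        """10 silent frames at rate 0.5 -> loglik = -sum(rate) = -5."""
        p = lnp_init(1)
        p.b[0] = np.log(0.5)
        w = LNPWindow(1, window=10)
        for _ in range(10):
            w.push(np.zeros(1), np.zeros(8))
        assert lnp_loglik(p, w) == pytest.approx(-5.0)

    def test_one_spike_per_frame_unit_rate(self):
        p = lnp_init(1)  # b=0 -> rate 1 with no history/coupling drive
        T = 12
        w = LNPWindow(1, window=T)
        for _ in range(T):
            w.push(np.ones(1), np.zeros(8))
        # with history weights zero the drive stays 0: each frame adds -1
        assert lnp_loglik(p, w) == pytest.approx(-T)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_double_loop(self, seed):
        pop, w = filled_window(4, 40, seed=seed)
        p = gen_random_lnp_params(4, seed=seed + 10)
        S, X, w0 = w.arrays()
        assert lnp_loglik(p, w) == pytest.approx(
            naive_loglik(p, S, X, w0), abs=1e-10
        )

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            lnp_loglik(lnp_init(1), LNPWindow(1, window=10))


class TestGradient:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_central_finite_differences(self, seed):
        pop, w = filled_window(4, 30, seed=seed)
        p = gen_random_lnp_params(4, seed=seed + 5)
        g = lnp_gradient(p, w)
        eps = 1e-6
        rng = np.random.default_rng(seed)
        for name in ("b", "K", "H", "W"):
            arr = getattr(p, name)
            grad = getattr(g, name)
            for _ in range(5):
                idx = tuple(rng.integers(s) for s in arr.shape)
                if name == "W" and idx[0] == idx[1]:
                    continue
                p_hi = p.copy(); getattr(p_hi, name)[idx] += eps
                p_lo = p.copy(); getattr(p_lo, name)[idx] -= eps
                fd = (lnp_loglik(p_hi, w) - lnp_loglik(p_lo, w)) / (2 * eps)
                denom = max(abs(fd), 1.0)
                assert abs(grad[idx] - fd) / denom < 1e-5, (name, idx)

    def test_stationary_point_step_is_tiny(self):
        """Near the MLE the gradient, and hence the update, vanishes."""
        pop, w = filled_window(3, 60, seed=2)
        from neuroloop.models.lnp import lnp_fit_offline

        mle, _ = lnp_fit_offline(pop.spikes, pop.stim)
        before = mle.copy()
        lnp_sgd_step(mle, w, step=1e-5)
        # window gradient differs from the full-data optimum gradient, but
        # the parameter change is bounded by step * ||window gradient||
        g = lnp_gradient(before, w)
        total = sum(
            np.abs(getattr(mle, a) - getattr(before, a)).max() for a in "bKHW"
        )
        gnorm = max(np.abs(v).max() for v in (g.b, g.K, g.H, g.W))
        assert total <= 4 * 1e-5 * gnorm + 1e-12

    def test_diag_coupling_stays_zero(self):
        pop, w = filled_window(4, 30, seed=3)
        p = gen_random_lnp_params(4, seed=1)
        for _ in range(5):
            lnp_sgd_step(p, w, step=1e-3)
        np.testing.assert_array_equal(np.diag(p.W), 0.0)

    def test_window_length_bounds(self):
        with pytest.raises(ValueError):
            LNPWindow(2, window=5)
        with pytest.raises(ValueError):
            LNPWindow(2, window=101)
        pop = gen_lnp_population(2, 5, seed=0)
        w = LNPWindow(2, window=10)
        for t in range(5):  # fewer frames than the 10-frame minimum
            w.push(pop.spikes[t], pop.stim[t])
        with pytest.raises(ValueError):
            lnp_sgd_step(lnp_init(2), w)


class TestTopConnections:
    def test_magnitude_order(self):
        W = np.array([[0.0, 3.0, -5.0, 1.0]])
        assert top_connections(W, 0, m=3) == [2, 1, 3]

    def test_zero_row_index_tie_break(self):
        W = np.zeros((4, 4))
        assert top_connections(W, 0, m=3) == [1, 2, 3]

    def test_m_one_is_argmax(self):
        W = np.array([[0.0, -9.0, 2.0, 1.0]])
        assert top_connections(W, 0, m=1) == [1]

    def test_m_too_large_returns_all(self):
        logged = []
        W = np.zeros((3, 3))
        out = top_connections(W, 1, m=10, log=lambda k, d: logged.append(k))
        assert out == [0, 2] and logged


class TestFitter:
    def test_window_memory_bounded(self):
        fitter = LNPFitter(3, window=20)
        pop = gen_lnp_population(3, 200, seed=4)
        for t in range(200):
            fitter.update(pop.spikes[t], pop.stim[t])
        assert len(fitter.window._frames) <= 20 + 4  # window + history context

    def test_fitted_params_beat_initialization(self):
        """After streaming, the learned parameters assign the data a higher
        likelihood than the zero initialization (same evaluation window)."""
        pop = gen_lnp_population(8, 600, seed=5)
        fitter = LNPFitter(8)
        for t in range(600):
            fitter.update(pop.spikes[t], pop.stim[t])
        from neuroloop.models.lnp import lnp_init, lnp_loglik

        assert lnp_loglik(fitter.params, fitter.window) > lnp_loglik(
            lnp_init(8), fitter.window
        )
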