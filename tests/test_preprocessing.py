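"""Frame/event preprocessing: thresholds, Dice alignment, binning,
smoothing, running direction tuning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroloop.preprocessing import (
    BinaryImage,
    RoiMask,
    StimulusEvent,
    TuningCurve8,
    bin_spikes,
    block_downsample,
    dice_coefficient,
    extract_traces,
    gaussian_smooth,
    otsu_threshold,
    select_best_plane,
    tuning_to_color,
    update_direction_tuning,
)


def brute_force_otsu(img: np.ndarray) -> float:
    """Exhaustive between-class-variance maximizer over all candidate
    thresholds (independent oracle)."""
    values = np.unique(img)
    best_t, best_var = values[0], -1.0
    flat = img.ravel()
    for t in values[:-1]:
        lo, hi = flat[flat <= t], flat[flat > t]
        w0, w1 = len(lo) / len(flat), len(hi) / len(flat)
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return float(best_t)


class TestOtsu:
    def test_bimodal_two_valued(self):
        img = np.full((10, 10), 10.0)
        img.ravel()[:40] = 200.0
        out = otsu_threshold(img)
        assert 10 < out.threshold_used < 200
        assert out.pixels.mean() == pytest.approx(0.4)

    def test_idempotent_on_binary(self):
        img = (np.arange(100).reshape(10, 10) % 3 == 0).astype(float)
        once = otsu_threshold(img)
        twice = otsu_threshold(once.pixels)
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.ones((5, 5)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search_on_8bit(self, seed):
        rng = np.random.default_rng(seed)
        img = np.concatenate([
            rng.normal(80, 12, 600), rng.normal(190, 15, 400)
        ]).clip(0, 255).round().reshape(50, 20).astype(np.uint8)
        out = otsu_threshold(img)
        oracle_t = brute_force_otsu(img)
        np.testing.assert_array_equal(out.pixels.astype(bool), img > oracle_t)


class TestDice:
    def test_identity_is_one(self):
        m = np.zeros((4, 4)); m[1:3, 1:3] = 1
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((4, 4)); a[0, 0] = 1
        b = np.zeros((4, 4)); b[3, 3] = 1
        assert dice_coefficient(a, b) == 0.0

    def test_worked_example_point_six(self):
        """|X|=4, |Y|=6, |X∩Y|=3 -> 2*3/(4+6) = 0.6 on a 3x4 mask pair."""
        a = np.zeros((3, 4)); b = np.zeros((3, 4))
        a[0, :4] = 1                    # |X| = 4
        b[0, 1:4] = 1; b[1, :3] = 1     # |Y| = 6, overlap = 3
        assert dice_coefficient(a, b) == pytest.approx(0.6)

    def test_both_empty_convention(self):
        assert dice_coefficient(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((2, 2)), np.zeros((3, 3)))

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    def test_symmetric_and_bounded(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(16)]).reshape(4, 4)
        b = np.array([(bits_b >> i) & 1 for i in range(16)]).reshape(4, 4)
        d = dice_coefficient(a, b)
        assert d == dice_coefficient(b, a)
        assert 0.0 <= d <= 1.0
        assert (d == 1.0) == bool(np.array_equal(a, b)) or (a.sum() + b.sum() == 0)


class TestPlaneSelection:
    def _target(self):
        img = np.zeros((40, 40)); img[10:20, 10:20] = 100.0
        img += np.linspace(0, 1, 40)[None, :]
        return img

    def test_exact_plane_wins(self):
        img = self._target()
        shifted = [np.roll(img, s, axis=0) for s in (-4, -2, 0, 2, 4)]
        target = otsu_threshold(img)
        assert select_best_plane(shifted, [-6, -3, 0, 3, 6], target) == 2

    def test_tie_breaks_to_smallest_offset(self):
        img = self._target()
        target = otsu_threshold(img)
        idx = select_best_plane([img] * 5, [-6, -3, 0, 3, 6], target)
        assert idx == 2  # all identical: smallest |offset| wins

    def test_drift_up_to_20pct_of_height(self):
        img = self._target()
        target = otsu_threshold(img)
        drifts = [-8, -4, 0, 4, 8]  # up to 20% of 40 rows
        planes = [np.roll(img, d, axis=0) for d in drifts]
        assert select_best_plane(planes, drifts, target) == 2

    def test_empty_stack(self):
        with pytest.raises(ValueError):
            select_best_plane([], [], otsu_threshold(self._target()))


class TestDownsample:
    def test_paper_geometry(self):
        out = block_downsample(np.zeros((240, 320)), 2)
        assert out.shape == (120, 160)

    def test_constant_preserved(self):
        out = block_downsample(np.full((8, 8), 3.5), 4)
        np.testing.assert_allclose(out, 3.5)

    def test_block_mean(self):
        out = block_downsample(np.array([[1.0, 3.0], [5.0, 7.0]]), 2)
        assert out.shape == (1, 1) and out[0, 0] == 4.0

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            block_downsample(np.zeros((4, 4)), 0)


class TestExtractTraces:
    def test_constant_region(self):
        frame = np.full((10, 10), 50.0)
        mask = RoiMask(pixels=np.array([[2, 2], [2, 3], [3, 2]]), center=(2, 2), id=0)
        assert extract_traces(frame, [mask])[0] == 50.0

    def test_noise_free_movie_recovers_signals(self):
        from neuroloop.synthetic import gen_calcium_movie

        movie, truth = gen_calcium_movie(4, 120, noise_sd=0.0, seed=3)
        traces = np.array(
            [extract_traces(movie[t], truth.masks) for t in range(120)]
        ).T
        np.testing.assert_allclose(traces, truth.fluorescence, atol=1e-10)

    def test_empty_and_out_of_bounds_masks(self):
        frame = np.zeros((5, 5))
        with pytest.raises(ValueError):
            extract_traces(frame, [RoiMask(np.empty((0, 2), int), (0, 0), 7)])
        with pytest.raises(ValueError, match="3"):
            extract_traces(frame, [RoiMask(np.array([[9, 0]]), (0, 9), 3)])


class TestBinning:
    def test_worked_example(self):
        counts = bin_spikes(np.array([0.001, 0.004, 0.012]), 0.010, 0.020)
        np.testing.assert_array_equal(counts, [2, 1])

    def test_no_events(self):
        np.testing.assert_array_equal(bin_spikes(np.array([]), 0.01, 0.05), [0] * 5)

    def test_boundary_goes_to_upper_bin(self):
        counts = bin_spikes(np.array([0.010]), 0.010, 0.030)
        np.testing.assert_array_equal(counts, [0, 1, 0])

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            bin_spikes(np.array([-0.1, 0.1]), 0.01, 0.2)


class TestSmoothing:
    def test_constant_preserved(self):
        out = gaussian_smooth(np.full(200, 2.5), window=50)
        np.testing.assert_allclose(out, 2.5)

    def test_impulse_gives_unit_mass_kernel(self):
        x = np.zeros(201); x[100] = 1.0
        out = gaussian_smooth(x, window=50)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(out) == 100

    def test_interior_mass_conserved(self, rng):
        counts = rng.poisson(3.0, 400).astype(float)
        out = gaussian_smooth(counts, window=50)
        # away from the reflect-padded boundaries, mass is conserved
        assert out[50:-50].sum() == pytest.approx(
            counts[50:-50].sum(), abs=counts[25:-25].sum() * 0.02 + 1e-9
        )
        assert out.sum() == pytest.approx(counts.sum(), abs=1e-9)

    def test_window_longer_than_series(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros(10), window=50)


class TestDirectionTuning:
    def _event(self, angle=90.0, onset=20):
        return StimulusEvent(angle, angle, onset, 15, 19)

    def test_baseline_subtracted_response(self):
        trace = np.ones(40); trace[20:35] = 3.0
        curve = update_direction_tuning(trace, self._event(), TuningCurve8())
        assert curve.mean_response[2] == pytest.approx(2.0)
        assert curve.trial_counts[2] == 1

    def test_flat_trace_zero_response(self):
        curve = update_direction_tuning(np.ones(40), self._event(), TuningCurve8())
        assert curve.mean_response[2] == 0.0

    def test_running_mean_two_trials(self):
        curve = TuningCurve8()
        for resp in (1.0, 3.0):
            trace = np.zeros(40); trace[20:35] = resp
            curve = update_direction_tuning(trace, self._event(), curve)
        assert curve.mean_response[2] == pytest.approx(2.0)
        assert curve.trial_counts[2] == 2

    def test_running_equals_batch_mean(self, rng):
        """The running mean matches the batch mean over the same trials."""
        curve = TuningCurve8()
        responses = []
        for _ in range(17):
            r = rng.normal()
            trace = np.zeros(40); trace[20:35] = r
            responses.append(r)
            curve = update_direction_tuning(trace, self._event(), curve)
        assert curve.mean_response[2] == pytest.approx(np.mean(responses), abs=1e-12)

    def test_insufficient_history_skipped(self):
        logged = []
        curve = update_direction_tuning(
            np.ones(30), self._event(onset=5), TuningCurve8(),
            log=lambda k, d: logged.append(k),
        )
        assert curve.trial_counts.sum() == 0
        assert logged == ["tuning-skip"]


class TestTuningColor:
    def test_forward_maps_to_green(self):
        curve = TuningCurve8()
        curve.mean_response[0] = 1.0  # forward direction only
        r, g, b = tuning_to_color(curve)
        assert g > r and g > b

    def test_all_zero_is_black(self):
        assert tuning_to_color(TuningCurve8()) == (0.0, 0.0, 0.0)

    def test_opposed_responses_tie_break_and_brightness(self):
        curve = TuningCurve8()
        curve.mean_response[0] = 0.5
        curve.mean_response[4] = 0.5  # perfectly opposed
        rgb = tuning_to_color(curve, population_max=1.0)
        assert max(rgb) == pytest.approx(0.5)  # brightness from magnitude
        # tie resolves to the first maximum (forward -> green)
        assert rgb[1] == max(rgb)
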