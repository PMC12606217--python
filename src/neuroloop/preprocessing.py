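"""Frame-level streaming preprocessing.

Covers the image side of a two-photon experiment (Otsu binarization,
Sørensen–Dice plane alignment against a reference image, block
downsampling, ROI trace extraction) and the event side (spike binning,
Gaussian-kernel rate smoothing, running direction-selectivity tuning with
hue/brightness color coding).

Trace extraction here is a deliberate simple stand-in: the mean intensity
over each known ROI footprint.  It performs no motion correction, source
extraction, or deconvolution — synthetic movies come with ground-truth
masks, and spike counts for model fitting come from the generators.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "BinaryImage",
    "RoiMask",
    "StimulusEvent",
    "TuningCurve8",
    "otsu_threshold",
    "dice_coefficient",
    "select_best_plane",
    "block_downsample",
    "extract_traces",
    "bin_spikes",
    "gaussian_smooth",
    "update_direction_tuning",
    "tuning_to_color",
    "DIRECTIONS_DEG",
]

DIRECTIONS_DEG = np.arange(0, 360, 45)  # the 8 whole-field motion directions


@dataclass
class BinaryImage:
    pixels: np.ndarray  # H x W of {0, 1}
    threshold_used: float


@dataclass
class RoiMask:
    """Pixel footprint of one neuron.  ``center`` is (x, y) = (col, row)."""

    pixels: np.ndarray  # (n, 2) array of (row, col)
    center: tuple[float, float]
    id: int


@dataclass
class StimulusEvent:
    angle_left: float
    angle_right: float
    onset_frame: int
    moving_frames: int
    stationary_frames: int

    @property
    def whole_field(self) -> bool:
        return self.angle_left == self.angle_right


@dataclass
class TuningCurve8:
    """Running mean response per motion direction (0, 45, ..., 315 deg)."""

    mean_response: np.ndarray = field(default_factory=lambda: np.zeros(8))
    trial_counts: np.ndarray = field(default_factory=lambda: np.zeros(8, dtype=int))
    color: tuple[float, float, float] = (0.0, 0.0, 0.0)


def otsu_threshold(img: np.ndarray) -> BinaryImage:
    """Binarize with the Otsu threshold (maximal between-class variance).

    Pixels strictly above the threshold map to foreground (1).
    """
    img = np.asarray(img)
    if img.size == 0 or np.ptp(img) == 0:
        raise ValueError("constant image: Otsu threshold is undefined")
    t = threshold_otsu(img)
    return BinaryImage(pixels=(img > t).astype(np.uint8), threshold_used=float(t))


def dice_coefficient(a: BinaryImage | np.ndarray, b: BinaryImage | np.ndarray) -> float:
    """Sørensen–Dice overlap 2|X∩Y| / (|X| + |Y|) of two binary masks.

    Both-empty masks score 1 by convention (identical emptiness).
    """
    x = (a.pixels if isinstance(a, BinaryImage) else np.asarray(a)).astype(bool)
    y = (b.pixels if isinstance(b, BinaryImage) else np.asarray(b)).astype(bool)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    denom = int(x.sum()) + int(y.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / denom


def select_best_plane(
    planes: list[np.ndarray],
    offsets_um: list[float],
    target: BinaryImage,
) -> int:
    """Pick the imaging plane best aligned with the binarized reference.

    Each plane is Otsu-binarized and scored against ``target`` with the Dice
    coefficient; ties prefer the smallest |offset|, then the lower index.
    """
    if len(planes) == 0:
        raise ValueError("empty plane stack")
    if len(planes) != len(offsets_um):
        raise ValueError("planes and offsets differ in length")
    scores = [dice_coefficient(otsu_threshold(p), target) for p in planes]
    order = sorted(
        range(len(planes)),
        key=lambda i: (-scores[i], abs(offsets_um[i]), i),
    )
    return order[0]


def block_downsample(img: np.ndarray, factor: int) -> np.ndarray:
    """Mean-pool ``factor`` x ``factor`` blocks (trailing rows/cols cropped)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    h2, w2 = h - h % factor, w - w % factor
    img = img[:h2, :w2]
    return img.reshape(h2 // factor, factor, w2 // factor, factor).mean(axis=(1, 3))


def extract_traces(frame: np.ndarray, masks: list[RoiMask]) -> np.ndarray:
    """Per-ROI mean fluorescence of one frame, in mask order."""
    frame = np.asarray(frame)
    out = np.empty(len(masks))
    for i, m in enumerate(masks):
        px = np.asarray(m.pixels)
        if px.size == 0:
            raise ValueError(f"ROI {m.id}: empty mask")
        rows, cols = px[:, 0], px[:, 1]
        if (
            rows.min() < 0
            or cols.min() < 0
            or rows.max() >= frame.shape[0]
            or cols.max() >= frame.shape[1]
        ):
            raise ValueError(f"ROI {m.id}: mask out of frame bounds")
        out[i] = frame[rows, cols].mean()
    return out


def bin_spikes(events: np.ndarray, bin_width: float, t_end: float) -> np.ndarray:
    """Count spikes in half-open bins [k*w, (k+1)*w) covering [0, t_end)."""
    events = np.asarray(events, dtype=float)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if events.size and events.min() < 0:
        raise ValueError("negative spike times")
    n_bins = int(np.ceil(t_end / bin_width - 1e-12))
    counts = np.zeros(n_bins, dtype=int)
    kept = events[events < t_end]
    idx = np.floor(kept / bin_width).astype(int)
    np.add.at(counts, idx, 1)
    return counts


def gaussian_kernel(window: int, sigma: float) -> np.ndarray:
    """Truncated Gaussian kernel of odd length >= window, normalized to sum 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = window // 2
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(counts: np.ndarray, window: int = 50, sigma: float | None = None) -> np.ndarray:
    """Smooth binned counts into a firing-rate estimate.

    Convolution with a normalized truncated Gaussian (default sigma =
    window / 10 bins), reflect-padded so output length equals input length
    and interior mass is conserved.
    """
    counts = np.asarray(counts, dtype=float)
    if window > counts.shape[-1]:
        raise ValueError("window longer than the series")
    if sigma is None:
        sigma = window / 10.0
    k = gaussian_kernel(window, sigma)
    return ndimage.convolve1d(counts, k, axis=-1, mode="reflect")


def update_direction_tuning(
    trace: np.ndarray,
    event: StimulusEvent,
    curve: TuningCurve8,
    baseline_frames: int = 10,
    response_frames: int = 15,
    log=None,
) -> TuningCurve8:
    """Fold one whole-field stimulus trial into a running 8-direction curve.

    Response = mean over ``response_frames`` frames from onset, minus the
    mean over the ``baseline_frames`` frames directly before onset.  Events
    without enough pre-onset history are skipped (logged).
    """
    trace = np.asarray(trace, dtype=float)
    on = event.onset_frame
    if on - baseline_frames < 0 or on + response_frames > trace.shape[0]:
        if log is not None:
            log("tuning-skip", f"event at frame {on}: insufficient history")
        return curve
    if not event.whole_field:
        raise ValueError("8-direction tuning requires whole-field events")
    d = int(round(event.angle_left / 45.0)) % 8
    if event.angle_left % 45 != 0:
        raise ValueError("whole-field direction must be a multiple of 45 deg")
    baseline = trace[on - baseline_frames : on].mean()
    response = trace[on : on + response_frames].mean() - baseline
    n = curve.trial_counts[d]
    curve.mean_response[d] = (curve.mean_response[d] * n + response) / (n + 1)
    curve.trial_counts[d] = n + 1
    return curve


def tuning_to_color(
    curve: TuningCurve8,
    population_max: float | None = None,
    forward_hue: float = 1.0 / 3.0,
) -> tuple[float, float, float]:
    """Encode a tuning curve as RGB: hue = preferred direction, value =
    response magnitude.

    The hue wheel is anchored so the forward direction (0 deg) maps to green
    and other directions interpolate around the HSV wheel.  Brightness is the
    peak rectified response normalized by ``population_max`` (defaults to the
    curve's own peak).  All-zero (or all-suppressed) curves are black.
    """
    r = np.maximum(np.asarray(curve.mean_response, dtype=float), 0.0)
    if r.sum() == 0:
        return (0.0, 0.0, 0.0)
    theta = np.deg2rad(DIRECTIONS_DEG)
    vec = (r * np.exp(1j * theta)).sum()
    if abs(vec) < 1e-12:
        # perfectly opposed responses: fall back to the first maximum
        pref = np.deg2rad(DIRECTIONS_DEG[int(np.argmax(r))])
    else:
        pref = np.angle(vec)
    hue = (forward_hue + pref / (2 * np.pi)) % 1.0
    peak = r.max()
    if population_max is None or population_max <= 0:
        population_max = peak
    value = min(peak / population_max, 1.0)
    return colorsys.hsv_to_rgb(hue, 1.0, value)
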