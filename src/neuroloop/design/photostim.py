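"""Adaptive photostimulation: target scoring/selection, the repetition
protocol, photostim-derived tuning curves, and experiment phase control.

Targets are chosen among visually characterized neurons by (1) functional
type — the inner product of a neuron's tuning color array [r, g, b] with a
criteria basis (e.g. [-1, 1, -1] selects green, forward-preferring cells) —
and (2) opsin expression, proxied by summed red-channel intensity around
the soma.  The pipeline stops at emitting target coordinates plus spiral
parameters; galvo waveform synthesis belongs to the rig.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronRecord",
    "PhotostimEvent",
    "PhaseState",
    "NoTargetError",
    "select_photostim_target",
    "run_photostim_protocol",
    "compute_photostim_tuning",
    "phase_controller",
]


@dataclass
class NeuronRecord:
    id: int
    position: tuple[float, float]  # (x, y), x relative to field-of-view center
    color: tuple[float, float, float] = (0.0, 0.0, 0.0)
    opsin_intensity: float = 0.0
    responses: dict = field(default_factory=dict)  # grid index -> [responses]
    stimulated: bool = False


@dataclass
class PhotostimEvent:
    target_id: int
    coords: tuple[float, float]
    repetition: int
    time_s: float
    duration_ms: float = 250.0
    dwell_ms: float = 1.0

    def to_record(self) -> dict:
        return {
            "kind": "photostim",
            "target_id": self.target_id,
            "x": self.coords[0],
            "y": self.coords[1],
            "repetition": self.repetition,
            "time_s": self.time_s,
            "duration_ms": self.duration_ms,
            "dwell_ms": self.dwell_ms,
        }


class NoTargetError(LookupError):
    """No neuron passes the targeting filters; the caller may relax them."""


def select_photostim_target(
    records: list[NeuronRecord],
    criteria_basis: tuple[float, float, float] = (-1.0, 1.0, -1.0),
    x_range: tuple[float, float] = (-75.0, 75.0),
    intensity_threshold: float = 50.0,
    exclusions: set[int] | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "max",
    fresh_preference: float = 0.9,
) -> int:
    """Pick the next photostimulation target; returns its neuron id.

    Candidates must lie within ``x_range``, score positively against the
    ``criteria_basis`` color inner product, and exceed the opsin-intensity
    threshold.  ``mode="max"`` takes the most intensely expressing
    candidate; ``mode="random"`` draws uniformly among candidates.  Already
    stimulated neurons (``exclusions``) are preferentially — but not
    always — avoided.
    """
    if not records:
        raise NoTargetError("no neuron records")
    if mode not in ("max", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = rng if rng is not None else np.random.default_rng(1337)
    exclusions = exclusions or set()
    basis = np.asarray(criteria_basis, dtype=float)
    candidates = [
        r for r in records
        if x_range[0] < r.position[0] < x_range[1]
        and float(np.dot(r.color, basis)) > 0
        and r.opsin_intensity > intensity_threshold
    ]
    if not candidates:
        raise NoTargetError("no candidate passes the targeting filters")
    fresh = [r for r in candidates if r.id not in exclusions]
    if fresh and (len(fresh) == len(candidates) or rng.random() < fresh_preference):
        pool = fresh
    else:
        pool = candidates
    if mode == "max":
        return max(pool, key=lambda r: (r.opsin_intensity, -r.id)).id
    return pool[int(rng.integers(len(pool)))].id


def run_photostim_protocol(
    target: NeuronRecord,
    repetitions: int = 5,
    spacing_s: float = 15.0,
    duration_ms: float = 250.0,
    dwell_ms: float = 1.0,
    response_oracle=None,
    traces: np.ndarray | None = None,
    event_frames: list[int] | None = None,
    baseline_frames: int = 10,
    response_frames: int = 15,
) -> tuple[list[PhotostimEvent], np.ndarray]:
    """Emit the timed repetition events for one target and collect responses.

    Events are spaced ``spacing_s`` apart starting at t = 0.  Per-neuron
    responses come either from ``response_oracle(target_id)`` (one call per
    repetition, e.g. a simulated network) or from fluorescence ``traces``
    (shape (n_neurons, T)) with ``event_frames`` marking each repetition's
    onset; trace responses reuse the visual-analysis convention of a
    15-frame response window minus a 10-frame pre-event baseline.  The
    target is marked stimulated.
    """
    events = [
        PhotostimEvent(
            target_id=target.id,
            coords=target.position,
            repetition=rep,
            time_s=rep * spacing_s,
            duration_ms=duration_ms,
            dwell_ms=dwell_ms,
        )
        for rep in range(repetitions)
    ]
    per_event = []
    if response_oracle is not None:
        for _ in events:
            per_event.append(np.asarray(response_oracle(target.id), dtype=float))
    elif traces is not None and event_frames is not None:
        traces = np.asarray(traces, dtype=float)
        if len(event_frames) != repetitions:
            raise ValueError("need one onset frame per repetition")
        for on in event_frames:
            if on - baseline_frames < 0 or on + response_frames > traces.shape[1]:
                raise ValueError(f"event at frame {on}: insufficient trace coverage")
            base = traces[:, on - baseline_frames : on].mean(axis=1)
            resp = traces[:, on : on + response_frames].mean(axis=1)
            per_event.append(resp - base)
    else:
        raise ValueError("provide response_oracle or (traces, event_frames)")
    target.stimulated = True
    return events, np.asarray(per_event)


def compute_photostim_tuning(
    event_targets: list[int],
    event_responses: np.ndarray,
    target_peak_directions: dict[int, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Direction-indexed photostimulation tuning curves.

    For each of the 8 directions, a neuron's value is its mean response
    across all events whose target's visual tuning peak lies at that
    direction.  Returns (curves of shape (n_neurons, 8) with NaN in empty
    bins, event counts per bin).
    """
    event_responses = np.atleast_2d(np.asarray(event_responses, dtype=float))
    n_events, n_neurons = event_responses.shape
    if len(event_targets) != n_events:
        raise ValueError("one target id per event row required")
    curves = np.full((n_neurons, 8), np.nan)
    counts = np.zeros(8, dtype=int)
    sums = np.zeros((n_neurons, 8))
    for e, tid in enumerate(event_targets):
        d = int(round(target_peak_directions[tid] / 45.0)) % 8
        sums[:, d] += event_responses[e]
        counts[d] += 1
    filled = counts > 0
    curves[:, filled] = sums[:, filled] / counts[filled]
    return curves, counts


@dataclass
class PhaseState:
    phase: str = "characterization"  # or "photostimulation"
    threshold: float = 0.9


def phase_controller(state: PhaseState, completeness: float, log=None) -> PhaseState:
    """One-way switch from visual characterization to photostimulation once
    the fraction of neurons with trials in all 8 directions reaches the
    configured threshold."""
    if state.phase == "characterization" and completeness >= state.threshold:
        state.phase = "photostimulation"
        if log is not None:
            log("phase-switch", f"completeness={completeness:.3f}")
    return state
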