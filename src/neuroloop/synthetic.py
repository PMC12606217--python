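"""Synthetic data generators with ground truth.

Every estimator in the package can be scored without external data: these
generators produce calcium movies with known ROI footprints and spike
trains, stimulus protocols, binocular tuning surfaces on the toroidal
stimulus grid, LNP spiking populations with known coupling, low-rank
behavior-video/neural stream pairs, noisy limit-cycle trajectories, and
photostimulation response networks — each alongside the latent quantities
that generated it.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design.gp import GRID, N_POINTS
from .models.lnp import N_STIM, LNPParams, lnp_rate
from .preprocessing import DIRECTIONS_DEG, RoiMask, StimulusEvent

__all__ = [
    "ProtocolSpec",
    "gen_stim_protocol",
    "stimulus_onehot_series",
    "CalciumMovieTruth",
    "gen_calcium_movie",
    "TuningSurfaceTruth",
    "gen_tuning_surface",
    "gen_tuning_population",
    "LNPPopulationTruth",
    "gen_lnp_population",
    "gen_random_lnp_params",
    "BehaviorNeuralTruth",
    "gen_behavior_neural_pair",
    "LimitCycleTruth",
    "gen_limit_cycle",
    "LatentSpikingTruth",
    "gen_latent_driven_spikes",
    "PhotostimNetworkTruth",
    "gen_photostim_network",
]


# --------------------------------------------------------------------------
# stimulus protocols
# --------------------------------------------------------------------------

@dataclass
class ProtocolSpec:
    """Interleaved stationary/moving grating protocol.

    Defaults emulate the whole-field characterization protocol: 4.2 s of
    motion after 5.3 s stationary, imaged at 3.6 frames/s (so 15 moving
    frames per event); the adaptive-stimulation variant uses 5 s moving /
    10 s stationary instead.
    """

    n_directions: int = 8
    moving_s: float = 4.2
    stationary_s: float = 5.3
    frame_rate_hz: float = 3.6
    repetitions: int = 3

    def __post_init__(self):
        if min(self.moving_s, self.stationary_s, self.frame_rate_hz) <= 0:
            raise ValueError("durations and frame rate must be positive")


def gen_stim_protocol(spec: ProtocolSpec, seed: int = 0) -> list[StimulusEvent]:
    """Tile a session with whole-field motion events, direction order
    pseudorandom (each repetition block is a permutation of all directions)."""
    rng = np.random.default_rng(seed)
    directions = np.arange(spec.n_directions) * (360.0 / spec.n_directions)
    moving = int(round(spec.moving_s * spec.frame_rate_hz))
    stationary = int(round(spec.stationary_s * spec.frame_rate_hz))
    events = []
    t_frame = 0
    for _ in range(spec.repetitions):
        for d in rng.permutation(spec.n_directions):
            onset = t_frame + stationary
            events.append(
                StimulusEvent(
                    angle_left=float(directions[d]),
                    angle_right=float(directions[d]),
                    onset_frame=onset,
                    moving_frames=moving,
                    stationary_frames=stationary,
                )
            )
            t_frame = onset + moving
    return events


def stimulus_onehot_series(events: list[StimulusEvent], T: int) -> np.ndarray:
    """(T, 8) one-hot of the currently moving direction (zeros when
    stationary)."""
    X = np.zeros((T, N_STIM))
    for ev in events:
        d = int(round(ev.angle_left / 45.0)) % N_STIM
        lo, hi = ev.onset_frame, min(ev.onset_frame + ev.moving_frames, T)
        X[lo:hi, d] = 1.0
    return X


# --------------------------------------------------------------------------
# calcium movies
# --------------------------------------------------------------------------

@dataclass
class CalciumMovieTruth:
    masks: list[RoiMask]
    spikes: np.ndarray  # (n_rois, T)
    fluorescence: np.ndarray  # (n_rois, T) noise-free convolved signals
    preferred_directions: np.ndarray  # (n_rois,) degrees
    events: list[StimulusEvent]


def _disk(center_rc: tuple[int, int], radius: int, H: int, W: int) -> np.ndarray:
    r0, c0 = center_rc
    rr, cc = np.mgrid[0:H, 0:W]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return np.argwhere(inside)


def gen_calcium_movie(
    n_rois: int,
    T_frames: int,
    H: int = 64,
    W: int = 64,
    decay_tau_frames: float = 7.0,
    noise_sd: float = 0.0,
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    roi_radius: int = 3,
    base_rate: float = 0.05,
    tuned_gain: float = 3.0,
) -> tuple[np.ndarray, CalciumMovieTruth]:
    """Simulate a movie of disk-shaped, direction-tuned ROIs.

    Spikes are Poisson per frame with rate = base + gain * von-Mises tuning
    of the currently moving direction; fluorescence is the spike train
    convolved with a single-exponential kernel (GCaMP6s-like decay);
    frames add i.i.d. Gaussian noise of sd ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    protocol = protocol or ProtocolSpec()
    events = gen_stim_protocol(protocol, seed=seed)
    # non-overlapping disk placement on a jittered lattice
    margin = roi_radius + 1
    pitch = 2 * roi_radius + 3
    slots = [
        (r, c)
        for r in range(margin, H - margin, pitch)
        for c in range(margin, W - margin, pitch)
    ]
    if n_rois > len(slots):
        raise ValueError(
            f"cannot place {n_rois} disjoint ROIs on a {H}x{W} frame"
        )
    chosen = [slots[i] for i in rng.choice(len(slots), n_rois, replace=False)]
    masks = [
        RoiMask(pixels=_disk(rc, roi_radius, H, W), center=(rc[1], rc[0]), id=i)
        for i, rc in enumerate(chosen)
    ]
    prefs = rng.choice(DIRECTIONS_DEG, n_rois)
    # per-frame rates
    stim = stimulus_onehot_series(events, T_frames)  # (T, 8)
    theta = np.deg2rad(DIRECTIONS_DEG)
    rates = np.full((n_rois, T_frames), base_rate)
    for i in range(n_rois):
        tuning = np.exp(2.0 * (np.cos(theta - np.deg2rad(prefs[i])) - 1.0))
        rates[i] += tuned_gain * (stim @ tuning)
    spikes = rng.poisson(rates).astype(float)
    kernel = np.exp(-np.arange(0, int(6 * decay_tau_frames)) / decay_tau_frames)
    fluor = np.array(
        [np.convolve(spikes[i], kernel)[:T_frames] for i in range(n_rois)]
    )
    movie = np.zeros((T_frames, H, W))
    for i, m in enumerate(masks):
        movie[:, m.pixels[:, 0], m.pixels[:, 1]] += fluor[i][:, None]
    if noise_sd > 0:
        movie += noise_sd * rng.standard_normal(movie.shape)
    truth = CalciumMovieTruth(
        masks=masks, spikes=spikes, fluorescence=fluor,
        preferred_directions=prefs.astype(float), events=events,
    )
    return movie, truth


# --------------------------------------------------------------------------
# binocular tuning surfaces (torus)
# --------------------------------------------------------------------------

@dataclass
class TuningSurfaceTruth:
    surface: np.ndarray  # (24, 24) noise-free response surface
    peak: int  # linear grid index of the true maximum
    width: float  # grid steps
    amplitude: float
    noise_sd: float

    def respond(self, p: int, rng: np.random.Generator) -> float:
        return float(self.surface.ravel()[p] + self.noise_sd * rng.standard_normal())


def gen_tuning_surface(
    seed: int = 0,
    width_range: tuple[float, float] = (2.0, 4.0),
    amplitude: float = 1.0,
    baseline: float = 0.0,
    noise_sd: float = 0.2,
    peak: int | None = None,
) -> TuningSurfaceTruth:
    """Wrapped-Gaussian bump on the 24 x 24 torus with a random peak.

    Trial responses are the surface value plus Gaussian noise of sd
    ``noise_sd`` (in units of the amplitude-1 surface).
    """
    rng = np.random.default_rng(seed)
    width = float(rng.uniform(*width_range))
    if peak is None:
        peak = int(rng.integers(N_POINTS))
    pi_, pj = peak // GRID, peak % GRID
    ii, jj = np.mgrid[0:GRID, 0:GRID]
    di = np.abs(ii - pi_)
    dj = np.abs(jj - pj)
    di = np.minimum(di, GRID - di)
    dj = np.minimum(dj, GRID - dj)
    surface = baseline + amplitude * np.exp(-(di**2 + dj**2) / (2 * width**2))
    return TuningSurfaceTruth(
        surface=surface, peak=peak, width=width, amplitude=amplitude,
        noise_sd=noise_sd * amplitude,
    )


def gen_tuning_population(
    n_neurons: int,
    seed: int = 0,
    noise_sd: float = 0.2,
    width_range: tuple[float, float] = (2.0, 4.0),
    shared_peak: int | None = None,
):
    """A population of tuning surfaces plus a shared response oracle.

    ``oracle(p)`` returns every neuron's noisy response to grid stimulus
    ``p`` — the population-sharing assumption of the closed-loop design.
    """
    rng = np.random.default_rng(seed)
    truths = [
        gen_tuning_surface(
            seed=int(rng.integers(2**31)), width_range=width_range,
            noise_sd=noise_sd, peak=shared_peak,
        )
        for _ in range(n_neurons)
    ]
    flat = np.array([t.surface.ravel() for t in truths])  # (n, 576)
    noise = np.array([t.noise_sd for t in truths])

    def oracle(p: int) -> np.ndarray:
        return flat[:, p] + noise * rng.standard_normal(n_neurons)

    return truths, oracle


# --------------------------------------------------------------------------
# LNP populations
# --------------------------------------------------------------------------

@dataclass
class LNPPopulationTruth:
    params: LNPParams
    spikes: np.ndarray  # (T, n)
    stim: np.ndarray  # (T, 8)


def gen_random_lnp_params(
    n: int,
    seed: int = 0,
    base_rate: float = 0.5,
    coupling_scale: float = 0.2,
    coupling_density: float = 0.3,
    stim_scale: float = 0.5,
    hist_scale: float = 0.2,
) -> LNPParams:
    """Random stable LNP parameters (|W| spectral radius scaled below 0.9)."""
    rng = np.random.default_rng(seed)
    W = rng.normal(0, coupling_scale, (n, n))
    W *= rng.random((n, n)) < coupling_density
    np.fill_diagonal(W, 0.0)
    radius = np.max(np.abs(np.linalg.eigvals(np.abs(W))))
    if radius >= 0.9:
        W *= 0.85 / radius
    return LNPParams(
        b=np.full(n, np.log(base_rate)),
        K=rng.normal(0, stim_scale, (n, N_STIM)),
        H=-np.abs(rng.normal(0, hist_scale, (n, 4))),  # refractory-ish
        W=W,
    )


def gen_lnp_population(
    n: int,
    T: int,
    true_params: LNPParams | None = None,
    stim: np.ndarray | None = None,
    seed: int = 0,
) -> LNPPopulationTruth:
    """Simulate Poisson spike counts from the LNP generative model."""
    rng = np.random.default_rng(seed)
    params = true_params or gen_random_lnp_params(n, seed=seed)
    radius = np.max(np.abs(np.linalg.eigvals(np.abs(params.W))))
    if radius >= 0.9:
        raise ValueError(
            f"|W| spectral radius {radius:.2f} >= 0.9: reduce coupling "
            "weights for a stable simulation"
        )
    if stim is None:
        spec = ProtocolSpec(repetitions=max(1, T // 272))
        stim = stimulus_onehot_series(gen_stim_protocol(spec, seed), T)
    spikes = np.zeros((T, n))
    hist = np.zeros((n, 4))
    for t in range(T):
        prev = spikes[t - 1] if t > 0 else np.zeros(n)
        rate = lnp_rate(params, stim[t], hist, prev)
        if np.any(rate > 1e6):
            raise ValueError("divergent rates; use smaller weights")
        spikes[t] = rng.poisson(rate)
        hist = np.column_stack([spikes[t], hist[:, :3]])
    return LNPPopulationTruth(params=params, spikes=spikes, stim=stim)


# --------------------------------------------------------------------------
# behavior-video / neural stream pairs
# --------------------------------------------------------------------------

@dataclass
class BehaviorNeuralTruth:
    loadings: np.ndarray  # (rank, H, W) spatial components
    latents: np.ndarray  # (T, rank) time courses
    B: np.ndarray  # (rank, n_neurons) regression map
    loading_masks: np.ndarray  # (rank, H, W) boolean localized regions


def gen_behavior_neural_pair(
    H: int = 24,
    W: int = 32,
    rank: int = 3,
    n_neurons: int = 10,
    T: int = 600,
    true_B: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, BehaviorNeuralTruth]:
    """Low-rank video (localized spatial blobs x smooth latents) paired with
    neural traces that are a linear readout of the same latents."""
    rng = np.random.default_rng(seed)
    if rank > min(H * W, T):
        raise ValueError("rank exceeds data dimensions")
    loadings = np.zeros((rank, H, W))
    masks = np.zeros((rank, H, W), dtype=bool)
    rr, cc = np.mgrid[0:H, 0:W]
    for r in range(rank):
        r0 = rng.integers(H // 6, 5 * H // 6)
        c0 = rng.integers(W // 6, 5 * W // 6)
        s = max(2.0, min(H, W) / 10)
        blob = np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * s**2)))
        loadings[r] = blob / np.linalg.norm(blob)
        masks[r] = blob > 0.1 * blob.max()
    t = np.arange(T)
    # distinct slow oscillations keep latents linearly independent
    latents = np.column_stack(
        [np.sin(2 * np.pi * t / (40 + 17 * r) + rng.uniform(0, 2 * np.pi))
         * (2.0 - 0.3 * r) for r in range(rank)]
    )
    B = true_B if true_B is not None else rng.normal(0, 1, (rank, n_neurons))
    frames = np.tensordot(latents, loadings, axes=(1, 0))  # (T, H, W)
    neural = latents @ B  # (T, n_neurons)
    if noise > 0:
        frames = frames + noise * rng.standard_normal(frames.shape)
        neural = neural + noise * rng.standard_normal(neural.shape)
    truth = BehaviorNeuralTruth(loadings=loadings, latents=latents, B=B,
                                loading_masks=masks)
    return frames, neural, truth


# --------------------------------------------------------------------------
# limit-cycle trajectories
# --------------------------------------------------------------------------

@dataclass
class LimitCycleTruth:
    period: float  # samples
    clean: np.ndarray  # (T, dims) noise-free trajectory
    basis: np.ndarray  # (dims, 2) embedding of the planar cycle


def gen_limit_cycle(
    T: int,
    dims: int = 2,
    noise_sd: float = 0.05,
    period: float = 100.0,
    radius: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, LimitCycleTruth]:
    """Noisy harmonic limit cycle embedded in ``dims`` dimensions by a
    random rotation."""
    if dims < 2:
        raise ValueError("dims must be >= 2")
    rng = np.random.default_rng(seed)
    t = np.arange(T)
    planar = radius * np.column_stack(
        [np.cos(2 * np.pi * t / period), np.sin(2 * np.pi * t / period)]
    )
    basis = np.linalg.qr(rng.standard_normal((dims, dims)))[0][:, :2]
    clean = planar @ basis.T
    traj = clean + noise_sd * rng.standard_normal((T, dims))
    return traj, LimitCycleTruth(period=period, clean=clean, basis=basis)


@dataclass
class LatentSpikingTruth:
    latents: np.ndarray  # (T, 2) driving trajectory at resolution dt
    loadings: np.ndarray  # (2, n_units)
    rates_hz: np.ndarray  # (T, n_units)
    period_s: float


def gen_latent_driven_spikes(
    n_units: int = 30,
    duration_s: float = 120.0,
    period_s: float = 1.0,
    rate_range_hz: tuple[float, float] = (5.0, 20.0),
    dt: float = 0.001,
    seed: int = 0,
) -> tuple[list[np.ndarray], LatentSpikingTruth]:
    """Spike times from a population driven by a slow latent limit cycle.

    Each unit's rate is an affine readout of a planar oscillation (period
    ``period_s``), mapped into ``rate_range_hz``; spikes are drawn by
    Bernoulli thinning at resolution ``dt``.  Emulates the structure of
    motor-cortex reach data: smooth low-dimensional latents underlying tens
    of spiking units.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, dt)
    z = np.column_stack(
        [np.cos(2 * np.pi * t / period_s), np.sin(2 * np.pi * t / period_s)]
    )
    C = rng.normal(0, 1.0, (2, n_units))
    drive = z @ C
    lo, hi = rate_range_hz
    rates = lo + (hi - lo) * (drive - drive.min()) / np.ptp(drive)
    spikes = [t[rng.random(len(t)) < rates[:, i] * dt] for i in range(n_units)]
    truth = LatentSpikingTruth(latents=z, loadings=C, rates_hz=rates,
                               period_s=period_s)
    return spikes, truth


# --------------------------------------------------------------------------
# photostimulation networks
# --------------------------------------------------------------------------

@dataclass
class PhotostimNetworkTruth:
    coupling: np.ndarray  # (n, n), coupling[target, j] = j's evoked response
    peak_directions: np.ndarray  # (n,) degrees, each neuron's visual peak
    records: list  # NeuronRecord per neuron


def gen_photostim_network(
    n: int,
    coupling: np.ndarray | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    density: float = 0.2,
):
    """Simulated photostimulation responses: stimulating neuron ``i`` evokes
    response ``coupling[i, j]`` (plus noise) in neuron ``j``.

    Returns (oracle, truth): ``oracle(target_id)`` draws one event's
    per-neuron response vector.  Neuron records carry positions, tuning
    colors, and opsin intensities for targeting tests.
    """
    from .design.photostim import NeuronRecord
    from .preprocessing import TuningCurve8, tuning_to_color

    rng = np.random.default_rng(seed)
    if coupling is None:
        coupling = np.abs(rng.normal(0, 1.0, (n, n)))
        coupling *= rng.random((n, n)) < density
        np.fill_diagonal(coupling, 0.0)
    else:
        coupling = np.asarray(coupling, dtype=float)
        if np.any(coupling < 0) or np.any(np.diag(coupling) != 0):
            raise ValueError("coupling must be non-negative with zero diagonal")
    prefs = rng.choice(DIRECTIONS_DEG, n).astype(float)
    records = []
    for i in range(n):
        curve = TuningCurve8()
        d = int(prefs[i] // 45)
        curve.mean_response[d] = 1.0
        records.append(
            NeuronRecord(
                id=i,
                position=(float(rng.uniform(-100, 100)), float(rng.uniform(0, 200))),
                color=tuning_to_color(curve),
                opsin_intensity=float(rng.uniform(0, 120)),
            )
        )
    truth = PhotostimNetworkTruth(
        coupling=coupling, peak_directions=prefs, records=records
    )

    def oracle(target_id: int) -> np.ndarray:
        resp = coupling[target_id].copy()
        if noise_sd > 0:
            resp = resp + noise_sd * rng.standard_normal(n)
        return resp

    return oracle, truth
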