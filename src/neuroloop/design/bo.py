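"""Closed-loop Bayesian optimization of visual stimuli.

Each neuron's binocular tuning surface is estimated online: present a
stimulus, record the evoked response, refit the GP, and pick the next
stimulus by the upper-confidence-bound rule f + kappa*sigma.  A stimulus
already sampled more than ``repeat_cap`` times falls back to a uniformly
random grid point.  Optimization of a neuron stops when the maximum
expected improvement over the best observed response drops below
``ei_threshold``, or after ``n_max`` stimuli (the neuron is then re-queued,
at most once).

Responses are population-shared: every neuron in the field of view responds
to every presented stimulus, so each presentation updates the tuning
history of *all* neurons, and later neurons often need only a handful of
extra stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .gp import GRID, N_POINTS, GPKernel, GPPosterior, angle_to_index, gp_fit

__all__ = [
    "BOConfig",
    "PopulationHistory",
    "ucb_select",
    "expected_improvement",
    "ei_stop",
    "bo_loop",
    "optimize_population",
    "peak_distance",
]


@dataclass
class BOConfig:
    """Closed-loop optimization settings.

    ``kappa`` weights exploration in the UCB score; a small value (default
    0.5) concentrates samples near the estimated peak, which is what sharpens
    peak localization once the shared history already covers the grid.
    Response units are arbitrary, so the kernel is rescaled per neuron: the
    prior signal variance follows the squared half-range of its observed
    responses (a flat response profile collapses the prior, firing the EI
    stop quickly), while the observation-noise variance is ``noise_frac``
    times the observed response variance — a deliberately conservative
    default (1.0) that over-smooths rather than chasing trial noise.
    ``min_own_samples`` forces each neuron's loop to present at least that
    many stimuli before the EI stopping rule may fire.
    """

    kappa: float = 0.5
    ei_threshold: float = 1e-2
    n_max: int = 30
    repeat_cap: int = 5
    seed: int = 1337
    per_neuron_attempts: int = 2
    population_cap: int = 300
    min_own_samples: int = 3
    kernel: GPKernel = field(default_factory=GPKernel)
    noise_frac: float = 1.0  # observation noise as a fraction of response var

    def init_stimuli(self, rng: np.random.Generator) -> list[int]:
        """8 whole-field stimuli (same angle to both eyes) at 45-degree
        spacing, presented in random order."""
        angles = np.arange(0, 360, 45)
        rng.shuffle(angles)
        return [angle_to_index(a, a) for a in angles]


class PopulationHistory:
    """Shared record of every presented stimulus and every neuron's responses."""

    def __init__(self, n_neurons: int):
        self.n_neurons = n_neurons
        self.observations: list[list[tuple[int, float]]] = [
            [] for _ in range(n_neurons)
        ]
        self.sample_counts = np.zeros(N_POINTS, dtype=int)
        self.presented: list[int] = []

    def record(self, p: int, responses: np.ndarray) -> None:
        """One stimulus presentation updates every neuron's history."""
        responses = np.asarray(responses, dtype=float)
        for i in range(self.n_neurons):
            self.observations[i].append((p, float(responses[i])))
        self.sample_counts[p] += 1
        self.presented.append(p)

    def _coverage_gap(self) -> float:
        """Largest toroidal distance (grid steps) from any grid point to the
        nearest presented stimulus; infinite before the first presentation."""
        pts = np.unique(np.nonzero(self.sample_counts)[0])
        if pts.size == 0:
            return np.inf
        idx = np.arange(N_POINTS)
        xi, yi = idx // GRID, idx % GRID
        px, py = pts // GRID, pts % GRID
        dx = np.abs(xi[:, None] - px[None, :])
        dy = np.abs(yi[:, None] - py[None, :])
        dx = np.minimum(dx, GRID - dx)
        dy = np.minimum(dy, GRID - dy)
        return float(np.sqrt((dx**2 + dy**2).min(axis=1).max()))

    def kernel_for(self, i: int, config: BOConfig) -> GPKernel:
        """Kernel rescaled to this neuron's responses.

        Fluorescence response units are arbitrary, so the observation noise
        follows the observed response variance, and the prior signal
        variance follows the squared half-range of the responses — a neuron
        whose responses are flat gets a collapsed prior, so the
        expected-improvement stop fires quickly.  The collapse is only
        allowed once presented stimuli cover the grid at the kernel scale;
        until then a flat history is indistinguishable from an unluckily
        sampled narrow bump, and the prior keeps its unit scale to drive
        exploration.
        """
        ys = np.array([y for _, y in self.observations[i]], dtype=float)
        if len(ys) > 1:
            var = float(np.var(ys))
            half_range_sq = float(np.ptp(ys)) ** 2 / 4.0
        else:
            var = half_range_sq = 1.0
        ls_steps = config.kernel.length_scale * GRID
        if self._coverage_gap() > 2.0 * ls_steps:
            half_range_sq = max(half_range_sq, 1.0)
        return GPKernel(
            length_scale=config.kernel.length_scale,
            signal_var=config.kernel.signal_var * max(half_range_sq, 1e-4),
            noise_var=max(config.noise_frac * var, 1e-6),
        )


def ucb_select(
    post: GPPosterior,
    kappa: float,
    sample_counts: np.ndarray,
    rng: np.random.Generator,
    repeat_cap: int = 5,
) -> int:
    """Argmax of f + kappa*sigma (ties to the lowest linear index); falls
    back to a uniform random grid point when the winner has already been
    sampled more than ``repeat_cap`` times."""
    score = (post.f + kappa * post.sigma).ravel()
    candidate = int(np.argmax(score))
    if sample_counts.ravel()[candidate] > repeat_cap:
        return int(rng.integers(N_POINTS))
    return candidate


def expected_improvement(post: GPPosterior, best_observed: float) -> np.ndarray:
    """Closed-form EI against the best observed response, per grid point."""
    f = post.f.ravel()
    s = post.sigma.ravel()
    ei = np.zeros(N_POINTS)
    pos = s > 0
    z = (f[pos] - best_observed) / s[pos]
    ei[pos] = (f[pos] - best_observed) * norm.cdf(z) + s[pos] * norm.pdf(z)
    return ei


def ei_stop(post: GPPosterior, best_observed: float, threshold: float = 1e-2) -> bool:
    """True when no grid point promises improvement above the threshold."""
    return bool(expected_improvement(post, best_observed).max() < threshold)


def _best_observed(obs: list[tuple[int, float]]) -> float:
    by_point: dict[int, list[float]] = {}
    for p, y in obs:
        by_point.setdefault(p, []).append(y)
    return max(float(np.mean(v)) for v in by_point.values())


def bo_loop(
    response_oracle,
    config: BOConfig,
    shared_history: PopulationHistory,
    neuron: int,
    rng: np.random.Generator | None = None,
) -> tuple[GPPosterior, int, int]:
    """Optimize one neuron's stimulus; returns (posterior, peak index,
    stimuli presented during this loop).

    ``response_oracle(p)`` presents grid stimulus ``p`` and returns the
    response vector of the whole population, which is appended to every
    neuron's shared history.  If nothing has been presented yet, the loop
    starts with the 8 whole-field initial stimuli.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    used = 0
    if not shared_history.presented:
        for p in config.init_stimuli(rng):
            shared_history.record(p, response_oracle(p))
            used += 1
    own = 0
    while True:
        kern = shared_history.kernel_for(neuron, config)
        obs = shared_history.observations[neuron]
        post = gp_fit(obs, kern)
        # stopping is evaluated after a presented stimulus, and only once
        # this neuron's own loop has contributed a few stimuli
        if (
            own >= config.min_own_samples
            and obs
            and ei_stop(post, _best_observed(obs), config.ei_threshold)
        ):
            break
        if used >= config.n_max:
            break
        p = ucb_select(post, config.kappa, shared_history.sample_counts, rng,
                       config.repeat_cap)
        shared_history.record(p, response_oracle(p))
        used += 1
        own += 1
    return post, post.peak_index, used


def optimize_population(
    population_oracle,
    n_neurons: int,
    config: BOConfig | None = None,
) -> tuple[dict[int, tuple[GPPosterior, int, int, bool]], PopulationHistory]:
    """Run the closed-loop optimization over a population.

    ``population_oracle(p)`` returns the response of every neuron to grid
    stimulus ``p``.  Neurons whose loop hits the stimulus cap without the EI
    criterion are re-queued once, after the rest of the population (by then
    the shared history is richer).  Returns a dict of per-neuron
    (posterior, peak index, stimuli used, converged) plus the shared
    :class:`PopulationHistory`.
    """
    config = config or BOConfig()
    rng = np.random.default_rng(config.seed)
    n_opt = min(n_neurons, config.population_cap)
    history = PopulationHistory(n_neurons)
    results: dict[int, tuple] = {}
    queue = list(range(n_opt))
    attempts = {i: 0 for i in queue}
    while queue:
        i = queue.pop(0)
        attempts[i] += 1
        try:
            post, peak, used = bo_loop(population_oracle, config, history, i, rng)
        except Exception:  # oracle failure: abort this neuron, maybe re-queue
            if attempts[i] < config.per_neuron_attempts:
                queue.append(i)
            continue
        obs = history.observations[i]
        converged = bool(obs) and ei_stop(post, _best_observed(obs), config.ei_threshold)
        results[i] = (post, peak, used, converged)
        if not converged and attempts[i] < config.per_neuron_attempts:
            queue.append(i)
    return results, history


def peak_distance(p: int | tuple[int, int], q: int | tuple[int, int]) -> float:
    """Euclidean distance between two grid points with circular boundary
    conditions, in grid-step units."""
    if np.isscalar(p):
        p = (int(p) // GRID, int(p) % GRID)
    if np.isscalar(q):
        q = (int(q) // GRID, int(q) % GRID)
    d = []
    for a, b in zip(p, q):
        delta = abs(a - b) % GRID
        d.append(min(delta, GRID - delta))
    return float(np.hypot(*d))
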