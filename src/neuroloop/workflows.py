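"""End-to-end streaming workflows composed from the package's estimators.

The latent-trajectory prediction workflow mirrors the electrophysiology
setting: raw spike times are binned (10 ms), smoothed into firing rates
(50-bin Gaussian window), reduced to a low-dimensional latent space with
streaming proSVD, and modeled with the Bubblewrap mixture-HMM, whose
horizon-k log predictive probability quantifies how far ahead the latent
trajectory can be forecast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models.bubblewrap import run_bubblewrap
from .models.prosvd import prosvd_init, prosvd_update
from .preprocessing import bin_spikes, gaussian_smooth

__all__ = ["HorizonReport", "spikes_to_rates", "latent_horizon_prediction"]


@dataclass
class HorizonReport:
    horizon_mean: dict[int, float]  # mean log pred prob, second half
    horizon_sd: dict[int, float]
    one_step_mean: float
    n_eval: int

    def degradation(self, h_far: int, h_near: int = 1) -> float:
        """Relative drop of mean log predictive probability between two
        horizons, as a fraction of the near-horizon magnitude."""
        near = self.horizon_mean[h_near]
        far = self.horizon_mean[h_far]
        return (near - far) / abs(near)


def spikes_to_rates(
    spike_times_by_unit: list[np.ndarray],
    bin_width: float = 0.010,
    t_end: float | None = None,
    smooth_window: int = 50,
    sigma: float | None = None,
) -> np.ndarray:
    """Bin per-unit spike times (10 ms default) and smooth with a Gaussian
    window into a (T, n_units) firing-rate array."""
    if t_end is None:
        t_end = max(float(s[-1]) for s in spike_times_by_unit if len(s)) + bin_width
    rates = [
        gaussian_smooth(
            bin_spikes(np.asarray(s, dtype=float), bin_width, t_end).astype(float),
            window=smooth_window,
            sigma=sigma,
        )
        for s in spike_times_by_unit
    ]
    return np.column_stack(rates)


def latent_horizon_prediction(
    rates: np.ndarray,
    k: int = 6,
    init_frames: int = 100,
    N: int = 50,
    lam: float = 1e-3,
    nu: float = 1e-3,
    eta: float = 8e-3,
    horizons: tuple[int, ...] = (1, 2, 3, 4, 5),
    seed: int = 0,
) -> HorizonReport:
    """Streaming proSVD to ``k`` dimensions, then Bubblewrap prediction.

    The first ``init_frames`` timepoints initialize the subspace; every
    later timepoint is embedded one at a time.  Per-horizon statistics are
    computed over the second half of the stream, where the models have
    stabilized.
    """
    rates = np.asarray(rates, dtype=float)
    T = rates.shape[0]
    state = prosvd_init(rates[:init_frames].T, k)
    latents = np.empty((T - init_frames, k))
    for t in range(init_frames, T):
        state = prosvd_update(state, rates[t])
        latents[t - init_frames] = state.Q.T @ rates[t]
    _, metrics, horizon_logp = run_bubblewrap(
        latents, N=N, lam=lam, nu=nu, eta=eta, horizons=horizons, seed=seed
    )
    half = len(metrics.log_pred_prob) // 2
    mean, sd = {}, {}
    n_eval = 0
    for h in horizons:
        scores = np.asarray(horizon_logp[h])
        tail = scores[len(scores) // 2:]
        mean[h] = float(tail.mean())
        sd[h] = float(tail.std())
        n_eval = max(n_eval, tail.size)
    return HorizonReport(
        horizon_mean=mean,
        horizon_sd=sd,
        one_step_mean=float(np.mean(metrics.log_pred_prob[half:])),
        n_eval=n_eval,
    )
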