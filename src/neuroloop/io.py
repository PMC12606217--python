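"""File-format helpers: TIFF movies, CSV traces/curves/events, NPZ states.

Movies travel as multi-page TIFF (one page per frame); fluorescence traces
and tuning curves as CSV with one row per ROI; stimulus events as CSV; and
estimator states as NPZ containers tagged with their kind.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .models.bubblewrap import BubblewrapState
from .models.lnp import LNPParams
from .models.prosvd import ProSVDState
from .models.ridge import RidgeState
from .preprocessing import StimulusEvent, TuningCurve8

__all__ = [
    "save_movie_tiff", "load_movie_tiff",
    "save_traces_csv", "load_traces_csv",
    "save_tuning_curves_csv", "load_tuning_curves_csv",
    "save_stimulus_events_csv", "load_stimulus_events_csv",
    "save_state_npz", "load_state_npz",
]


def save_movie_tiff(path, movie: np.ndarray) -> None:
    """Write a (T, H, W) movie as a multi-page TIFF, one page per frame."""
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))


def load_movie_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def save_traces_csv(path, traces: np.ndarray) -> None:
    """Write (n_rois, T) fluorescence traces; one row per ROI."""
    traces = np.atleast_2d(np.asarray(traces))
    df = pd.DataFrame(traces)
    df.insert(0, "roi", np.arange(traces.shape[0]))
    df.to_csv(path, index=False)


def load_traces_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.drop(columns=["roi"]).to_numpy(dtype=float)


def save_tuning_curves_csv(path, curves: list[TuningCurve8]) -> None:
    rows = []
    for i, c in enumerate(curves):
        row = {"roi": i}
        for d in range(8):
            row[f"mean_{d * 45}"] = c.mean_response[d]
            row[f"trials_{d * 45}"] = c.trial_counts[d]
        row["r"], row["g"], row["b"] = c.color
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_tuning_curves_csv(path) -> list[TuningCurve8]:
    df = pd.read_csv(path)
    curves = []
    for _, row in df.iterrows():
        c = TuningCurve8(
            mean_response=np.array([row[f"mean_{d * 45}"] for d in range(8)]),
            trial_counts=np.array(
                [row[f"trials_{d * 45}"] for d in range(8)], dtype=int
            ),
            color=(row["r"], row["g"], row["b"]),
        )
        curves.append(c)
    return curves


def save_stimulus_events_csv(path, events: list[StimulusEvent]) -> None:
    pd.DataFrame(
        [
            {
                "angle_left": e.angle_left,
                "angle_right": e.angle_right,
                "onset_frame": e.onset_frame,
                "moving_frames": e.moving_frames,
                "stationary_frames": e.stationary_frames,
            }
            for e in events
        ]
    ).to_csv(path, index=False)


def load_stimulus_events_csv(path) -> list[StimulusEvent]:
    df = pd.read_csv(path)
    return [
        StimulusEvent(
            angle_left=row.angle_left,
            angle_right=row.angle_right,
            onset_frame=int(row.onset_frame),
            moving_frames=int(row.moving_frames),
            stationary_frames=int(row.stationary_frames),
        )
        for row in df.itertuples()
    ]


# -- estimator state containers -------------------------------------------

def save_state_npz(path, state) -> None:
    """Serialize a ProSVD / ridge / LNP / Bubblewrap state to NPZ."""
    if isinstance(state, ProSVDState):
        np.savez(path, kind="prosvd", Q=state.Q, B=state.B, k=state.k,
                 seen=state.seen)
    elif isinstance(state, RidgeState):
        np.savez(path, kind="ridge", G=state.G, C=state.C, lam=state.lam,
                 n_obs=state.n_obs)
    elif isinstance(state, LNPParams):
        np.savez(path, kind="lnp", b=state.b, K=state.K, H=state.H,
                 W=state.W, step=state.step)
    elif isinstance(state, BubblewrapState):
        np.savez(
            path, kind="bubblewrap", mu=state.mu, Sigma=state.Sigma,
            A=state.A, alpha=state.alpha, lam=state.lam, nu=state.nu,
            eta=state.eta, n_w=state.n_w, m_w=state.m_w, S_w=state.S_w,
            Sigma0=state.Sigma0, occupancy=state.occupancy,
            recent_mass=state.recent_mass, steps=state.steps,
        )
    else:
        raise TypeError(f"cannot serialize {type(state).__name__}")


def load_state_npz(path):
    with np.load(path) as data:
        kind = str(data["kind"])
        if kind == "prosvd":
            return ProSVDState(Q=data["Q"], B=data["B"], k=int(data["k"]),
                               seen=int(data["seen"]))
        if kind == "ridge":
            return RidgeState(G=data["G"], C=data["C"],
                              lam=float(data["lam"]), n_obs=int(data["n_obs"]))
        if kind == "lnp":
            return LNPParams(b=data["b"], K=data["K"], H=data["H"],
                             W=data["W"], step=float(data["step"]))
        if kind == "bubblewrap":
            N, k = data["mu"].shape
            state = BubblewrapState(
                mu=data["mu"], Sigma=data["Sigma"], A=data["A"],
                alpha=data["alpha"], lam=float(data["lam"]),
                nu=float(data["nu"]), eta=float(data["eta"]), N=N, k=k,
                n_w=data["n_w"], m_w=data["m_w"], S_w=data["S_w"],
                Sigma0=data["Sigma0"], occupancy=data["occupancy"],
                recent_mass=data["recent_mass"], steps=int(data["steps"]),
                _chol=np.zeros((N, k, k)), _logdet=np.zeros(N),
            )
            for j in range(N):
                state.refresh_tile(j)
            return state
    raise ValueError(f"unknown state kind {kind!r}")
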