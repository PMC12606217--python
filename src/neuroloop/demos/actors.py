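"""Actor implementations for the packaged desk-scale demo pipelines.

Each demo pipeline wires a synthetic source to the corresponding streaming
analysis actor(s); actors that receive an ``out_dir`` parameter write their
metrics (CSV / JSON-lines) and summary plots (PNG) during teardown.
"""

from __future__ import annotations

import json
import os

import numpy as np

from ..design.bo import BOConfig, PopulationHistory, _best_observed, ei_stop, ucb_select
from ..design.gp import gp_fit
from ..design.photostim import (
    PhaseState,
    compute_photostim_tuning,
    phase_controller,
    run_photostim_protocol,
    select_photostim_target,
)
from ..models.bubblewrap import PredictionMetrics, bw_entropy, bw_init, bw_update
from ..models.lnp import LNPFitter
from ..models.prosvd import prosvd_init, prosvd_update
from ..models.ridge import (
    project_coefficients_to_pixels,
    ridge_coefficients,
    ridge_init,
    ridge_update,
)
from ..orchestration.actors import Actor
from ..preprocessing import TuningCurve8, block_downsample, tuning_to_color, update_direction_tuning
from .. import synthetic
from ..design.bo import peak_distance

__all__ = [
    "LNPPopulationSource", "LNPActor",
    "BehaviorSource", "ProSVDActor", "RidgeActor",
    "LimitCycleSource", "BubblewrapActor",
    "StimulusPresenter", "BOActor",
    "CharacterizationSource", "TuningActor", "PhotostimActor",
    "FaultInjector", "CountingSink",
]


def _out_dir(actor: Actor) -> str | None:
    return actor.params.get("out_dir")


def _save_csv(path: str, header: list[str], rows) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def _save_png(path: str, plot_fn) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    plot_fn(ax)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# --------------------------------------------------------------------------
# fig2-style demo: streaming LNP fitting on a simulated population
# --------------------------------------------------------------------------

class LNPPopulationSource(Actor):
    is_source = True

    def setup(self):
        n = int(self.params.get("n_neurons", 12))
        T = int(self.params.get("n_frames", 800))
        seed = int(self.params.get("seed", 0))
        self.truth = synthetic.gen_lnp_population(n, T, seed=seed)
        self.put("lnp_truth", self.truth)
        self.T = T
        self.i = 0

    def step(self, message):
        if self.i >= self.T:
            self.done = True
            return
        frame = {
            "spikes": self.truth.spikes[self.i],
            "stim": self.truth.stim[self.i],
        }
        self.emit_payload("frames", frame)
        self.i += 1


class LNPActor(Actor):
    def setup(self):
        self.window_len = int(self.params.get("window", 100))
        self.base_step = float(self.params.get("base_step", 0.01))
        self.fitter = None

    def step(self, message):
        frame = self.get(message.keys[0])
        spikes, stim = frame["spikes"], frame["stim"]
        if self.fitter is None:
            self.fitter = LNPFitter(
                spikes.shape[0], window=self.window_len, base_step=self.base_step
            )
        self.fitter.update(spikes, stim)

    @property
    def loglik(self):
        return self.fitter.loglik if self.fitter else []

    def teardown(self):
        out = _out_dir(self)
        if not out or not self.loglik:
            return
        ll = np.asarray(self.loglik)
        ewma = np.empty_like(ll)
        acc = ll[0]
        for i, v in enumerate(ll):
            acc = 0.98 * acc + 0.02 * v
            ewma[i] = acc
        _save_csv(
            os.path.join(out, "loglik.csv"),
            ["frame", "loglik", "ewma"],
            [(i, float(ll[i]), float(ewma[i])) for i in range(len(ll))],
        )
        truth_keys = self.store.topic_entries("lnp_truth")
        if truth_keys:
            truth = self.get(truth_keys[-1])
            mask = ~np.eye(truth.params.W.shape[0], dtype=bool)
            w_true = truth.params.W[mask]
            w_est = self.fitter.params.W[mask]
            if w_true.std() > 0 and w_est.std() > 0:
                r = float(np.corrcoef(w_true, w_est)[0, 1])
                with open(os.path.join(out, "lnp_summary.json"), "w") as fh:
                    json.dump({"coupling_pearson_r": r}, fh)
        _save_png(
            os.path.join(out, "loglik.png"),
            lambda ax: (ax.plot(ll, lw=0.5), ax.plot(ewma, lw=1.5),
                        ax.set_xlabel("frame"), ax.set_ylabel("window log-likelihood")),
        )


# --------------------------------------------------------------------------
# fig3-style demo: behavior video -> proSVD -> streaming ridge
# --------------------------------------------------------------------------

class BehaviorSource(Actor):
    is_source = True

    def setup(self):
        seed = int(self.params.get("seed", 0))
        self.H = int(self.params.get("height", 24))
        self.W = int(self.params.get("width", 32))
        T = int(self.params.get("n_frames", 600))
        frames, neural, truth = synthetic.gen_behavior_neural_pair(
            H=self.H, W=self.W,
            rank=int(self.params.get("rank", 3)),
            n_neurons=int(self.params.get("n_neurons", 10)),
            T=T, noise=float(self.params.get("noise", 0.01)), seed=seed,
        )
        self.frames, self.neural = frames, neural
        self.put("behavior_truth", truth)
        self.T = T
        self.i = 0

    def step(self, message):
        if self.i >= self.T:
            self.done = True
            return
        k_frame = self.put("video", self.frames[self.i])
        k_neural = self.put("neural", self.neural[self.i])
        self.emit([k_frame, k_neural])
        self.i += 1


class ProSVDActor(Actor):
    def setup(self):
        self.k = int(self.params.get("k", 10))
        self.init_frames = int(self.params.get("init_frames", 10))
        self.factor = int(self.params.get("downsample", 1))
        self._block = []
        self.prosvd = None
        self.basis_change = []
        self.image_shape = None

    def _flatten(self, frame):
        if self.factor > 1:
            frame = block_downsample(frame, self.factor)
        if self.image_shape is None:
            self.image_shape = frame.shape
        return np.asarray(frame, dtype=float).ravel()

    def step(self, message):
        frame = self._flatten(self.get(message.keys[0]))
        passthrough = list(message.keys[1:])
        if self.prosvd is None:
            self._block.append(frame)
            if len(self._block) >= max(self.init_frames, self.k):
                self.prosvd = prosvd_init(np.column_stack(self._block), self.k)
                self._block = None
            return
        Q_prev = self.prosvd.Q
        self.prosvd = prosvd_update(self.prosvd, frame)
        self.basis_change.append(float(np.linalg.norm(self.prosvd.Q - Q_prev)))
        latent = self.prosvd.Q.T @ frame
        self.emit([self.put("latents", latent), *passthrough])

    def teardown(self):
        if self.prosvd is not None:
            self.put("prosvd_q", self.prosvd.Q)
            self.put("prosvd_image_shape", self.image_shape)
        out = _out_dir(self)
        if out and self.basis_change:
            _save_csv(
                os.path.join(out, "basis_change.csv"),
                ["update", "frobenius_change"],
                list(enumerate(self.basis_change)),
            )


class RidgeActor(Actor):
    def setup(self):
        self.lam = float(self.params.get("lam", 1e-5))
        self.ridge = None

    def step(self, message):
        x = self.get(message.keys[0])
        y = self.get(message.keys[1])
        if self.ridge is None:
            self.ridge = ridge_init(x.shape[0], y.shape[0], lam=self.lam)
        ridge_update(self.ridge, x, y)

    def teardown(self):
        out = _out_dir(self)
        if not out or self.ridge is None or self.ridge.n_obs == 0:
            return
        beta = ridge_coefficients(self.ridge)
        qs = self.store.topic_entries("prosvd_q")
        shapes = self.store.topic_entries("prosvd_image_shape")
        if not qs or not shapes:
            return
        Q = self.get(qs[-1])
        shape = self.get(shapes[-1])
        wmap = project_coefficients_to_pixels(beta, Q, image_shape=tuple(shape))
        agg = np.sqrt((wmap**2).sum(axis=-1))
        truth_keys = self.store.topic_entries("behavior_truth")
        score = None
        if truth_keys:
            truth = self.get(truth_keys[-1])
            region = truth.loading_masks.any(axis=0)
            thresh = np.quantile(agg, 0.95)
            top = agg >= thresh
            score = float((top & region).sum() / max(top.sum(), 1))
            with open(os.path.join(out, "ridge_summary.json"), "w") as fh:
                json.dump({"top5pct_overlap": score}, fh)
            print(f"weight-map overlap of top-5% pixels with true regions: {score:.3f}")
        _save_png(
            os.path.join(out, "weight_map.png"),
            lambda ax: (ax.imshow(agg), ax.set_title("|pixel weights|")),
        )


# --------------------------------------------------------------------------
# fig4-style demo: trajectory stream -> Bubblewrap prediction
# --------------------------------------------------------------------------

class LimitCycleSource(Actor):
    is_source = True

    def setup(self):
        T = int(self.params.get("n_frames", 3000))
        self.traj, truth = synthetic.gen_limit_cycle(
            T,
            dims=int(self.params.get("dims", 6)),
            noise_sd=float(self.params.get("noise_sd", 0.05)),
            period=float(self.params.get("period", 100.0)),
            seed=int(self.params.get("seed", 0)),
        )
        self.put("cycle_truth", truth)
        self.T = T
        self.i = 0

    def step(self, message):
        if self.i >= self.T:
            self.done = True
            return
        self.emit_payload("trajectory", self.traj[self.i])
        self.i += 1


class BubblewrapActor(Actor):
    """Streams points through the mixture-HMM; delayed scoring gives honest
    horizon-k log predictive probabilities (predictions are frozen when made
    and scored when the future point arrives)."""

    def setup(self):
        self.N = int(self.params.get("n_tiles", 50))
        self.n_init = int(self.params.get("n_init", 20))
        self.horizons = tuple(self.params.get("horizons", (1, 2, 3, 4, 5)))
        self.eval_stride = int(self.params.get("eval_stride", 5))
        self.seed = int(self.params.get("seed", 0))
        self.bw = None
        self._init_buf = []
        self.metrics = PredictionMetrics()
        self.t = 0
        self._pending: dict[int, list] = {}
        self.horizon_scores: dict[int, list[float]] = {h: [] for h in self.horizons}

    def step(self, message):
        from scipy.special import logsumexp

        x = np.asarray(self.get(message.keys[0]), dtype=float)
        t = self.t
        # score predictions that targeted this arrival
        for h, logw, mu, chol, logdet in self._pending.pop(t, []):
            diffs = x[None, :] - mu
            z = np.linalg.solve(chol, diffs[:, :, None])[:, :, 0]
            ll = -0.5 * (x.shape[0] * np.log(2 * np.pi) + logdet + (z * z).sum(axis=1))
            self.horizon_scores[h].append(float(logsumexp(logw + ll)))
        if self.bw is None:
            self._init_buf.append(x)
            if len(self._init_buf) >= self.n_init:
                self.bw = bw_init(
                    np.asarray(self._init_buf), N=self.N, seed=self.seed
                )
                self._init_buf = None
            self.t += 1
            return
        self.bw, logp = bw_update(self.bw, x, log=self.log)
        self.metrics.append(logp, bw_entropy(self.bw))
        if self.horizons and t % self.eval_stride == 0:
            mu = self.bw.mu.copy()
            chol = self.bw._chol.copy()
            logdet = self.bw._logdet.copy()
            v = self.bw.alpha
            max_h = max(self.horizons)
            for h in range(1, max_h + 1):
                v = v @ self.bw.A
                if h in self.horizons:
                    logw = np.log(np.maximum(v, 1e-300))
                    self._pending.setdefault(t + h, []).append(
                        (h, logw, mu, chol, logdet)
                    )
        self.t += 1

    def teardown(self):
        out = _out_dir(self)
        if not out or not self.metrics.log_pred_prob:
            return
        m = self.metrics
        _save_csv(
            os.path.join(out, "bubblewrap_metrics.csv"),
            ["step", "log_pred_prob", "entropy_bits", "ewma_logp", "ewma_entropy"],
            [
                (i, m.log_pred_prob[i], m.entropy[i], m.ewma_logp[i], m.ewma_entropy[i])
                for i in range(len(m.log_pred_prob))
            ],
        )
        rows = []
        for h in self.horizons:
            s = np.asarray(self.horizon_scores[h])
            if s.size:
                rows.append((h, float(s.mean()), float(s.std()), s.size))
        _save_csv(
            os.path.join(out, "bubblewrap_horizons.csv"),
            ["horizon", "mean_log_pred_prob", "sd", "n"],
            rows,
        )
        _save_png(
            os.path.join(out, "bubblewrap_metrics.png"),
            lambda ax: (ax.plot(m.ewma_logp), ax.set_xlabel("step"),
                        ax.set_ylabel("EWMA log predictive probability")),
        )


# --------------------------------------------------------------------------
# fig5-style demo: closed-loop Bayesian stimulus optimization
# --------------------------------------------------------------------------

class StimulusPresenter(Actor):
    """Source inside the closed loop: presents stimuli (the 8 whole-field
    initializers, then whatever the BO actor commands via feedback) and
    publishes the population's responses."""

    is_source = True

    def setup(self):
        n = int(self.params.get("n_neurons", 30))
        seed = int(self.params.get("seed", 0))
        noise_sd = float(self.params.get("noise_sd", 0.2))
        self.truths, self.oracle = synthetic.gen_tuning_population(
            n, seed=seed, noise_sd=noise_sd
        )
        self.put("bo_truth", [t.peak for t in self.truths])
        cfg = BOConfig(seed=int(self.params.get("bo_seed", 1337)))
        rng = np.random.default_rng(cfg.seed)
        self._queue = cfg.init_stimuli(rng)

    def step(self, message):
        cmd = self.poll("in")
        if cmd is not None and cmd.keys:
            payload = self.get(cmd.keys[0])
            if payload.get("cmd") == "stop":
                self.done = True
                return
            self._queue.append(int(payload["p"]))
        if self._queue:
            p = self._queue.pop(0)
            self.emit_payload(
                "responses", {"p": p, "responses": self.oracle(p)}
            )


class BOActor(Actor):
    """Sequential per-neuron UCB/EI optimization driven by pipeline messages."""

    def setup(self):
        defaults = BOConfig()
        self.config = BOConfig(
            kappa=float(self.params.get("kappa", defaults.kappa)),
            ei_threshold=float(self.params.get("ei_threshold", defaults.ei_threshold)),
            n_max=int(self.params.get("n_max", defaults.n_max)),
            seed=int(self.params.get("bo_seed", defaults.seed)),
        )
        self.n_neurons = int(self.params.get("n_neurons", 30))
        self.history = PopulationHistory(self.n_neurons)
        self.rng = np.random.default_rng(self.config.seed)
        self.queue = list(range(min(self.n_neurons, self.config.population_cap)))
        self.attempts = {i: 0 for i in self.queue}
        self.current = None
        self.used = 0
        self.own = 0
        self.results = {}
        self._seen_inits = 0

    def _next_neuron(self):
        if self.current is not None:
            self.attempts[self.current] += 1
        while self.queue:
            self.current = self.queue.pop(0)
            self.used = 0
            self.own = 0
            return True
        self.current = None
        return False

    def _advance(self):
        """Fit / decide / emit until a stimulus command goes out or all
        neurons are done."""
        if self.current is None and not self._next_neuron():
            self._stop()
            return
        while True:
            i = self.current
            obs = self.history.observations[i]
            post = gp_fit(obs, self.history.kernel_for(i, self.config))
            converged = (
                self.own >= self.config.min_own_samples
                and bool(obs)
                and ei_stop(post, _best_observed(obs), self.config.ei_threshold)
            )
            if converged or self.used >= self.config.n_max:
                self.results[i] = {
                    "peak": post.peak_index,
                    "stimuli_used": self.used,
                    "converged": converged,
                }
                if not converged and self.attempts[i] + 1 < self.config.per_neuron_attempts:
                    self.queue.append(i)
                if not self._next_neuron():
                    self._stop()
                    return
                continue
            p = ucb_select(
                post, self.config.kappa, self.history.sample_counts,
                self.rng, self.config.repeat_cap,
            )
            self.emit_payload("commands", {"cmd": "present", "p": p})
            self.used += 1
            self.own += 1
            return

    def _stop(self):
        self.emit_payload("commands", {"cmd": "stop"})

    def step(self, message):
        payload = self.get(message.keys[0])
        self.history.record(int(payload["p"]), payload["responses"])
        if self._seen_inits < 8:
            self._seen_inits += 1
            if self._seen_inits < 8:
                return
            # all initial whole-field stimuli observed: start neuron 0
            self._next_neuron()
            self.used = 8
            self._advance()
            return
        self._advance()

    def teardown(self):
        out = _out_dir(self)
        if not out:
            return
        true_peaks = None
        keys = self.store.topic_entries("bo_truth")
        if keys:
            true_peaks = self.get(keys[-1])
        rows = []
        n_correct = 0
        for i, res in sorted(self.results.items()):
            dist = correct = ""
            if true_peaks is not None:
                dist = peak_distance(res["peak"], true_peaks[i])
                correct = int(dist <= 1.0)
                n_correct += correct
            rows.append(
                (i, res["stimuli_used"], res["peak"], res["converged"], dist, correct)
            )
        _save_csv(
            os.path.join(out, "bo_trace.csv"),
            ["neuron", "stimuli_used", "peak_index", "converged",
             "peak_distance", "correct"],
            rows,
        )
        if self.results and true_peaks is not None:
            frac = n_correct / len(self.results)
            print(f"BO peak recovery: {100 * frac:.1f}% of "
                  f"{len(self.results)} neurons within 1 grid step")


# --------------------------------------------------------------------------
# fig6-style demo: characterization phase -> adaptive photostimulation
# --------------------------------------------------------------------------

class CharacterizationSource(Actor):
    is_source = True

    def setup(self):
        n = int(self.params.get("n_rois", 20))
        seed = int(self.params.get("seed", 0))
        spec = synthetic.ProtocolSpec(repetitions=int(self.params.get("repetitions", 2)))
        self.events = synthetic.gen_stim_protocol(spec, seed=seed)
        last = self.events[-1]
        self.T = last.onset_frame + last.moving_frames
        rng = np.random.default_rng(seed)
        prefs = rng.choice(np.arange(0, 360, 45), n).astype(float)
        theta = np.deg2rad(np.arange(0, 360, 45))
        stim = synthetic.stimulus_onehot_series(self.events, self.T)
        traces = np.full((n, self.T), 1.0)
        for i in range(n):
            tuning = np.exp(3.0 * (np.cos(theta - np.deg2rad(prefs[i])) - 1.0))
            traces[i] += 2.0 * (stim @ tuning)
        traces += 0.05 * rng.standard_normal(traces.shape)
        self.traces = traces
        self.put("events", self.events)
        self.put("char_truth", {"preferred_directions": prefs})
        self.i = 0

    def step(self, message):
        if self.i >= self.T:
            self.done = True
            return
        self.emit_payload("traces", self.traces[:, self.i])
        self.i += 1


class TuningActor(Actor):
    def setup(self):
        self.buffer = []
        self.curves = None
        self.events = None
        self.next_event = 0
        self.phase = PhaseState(threshold=float(self.params.get("threshold", 0.9)))

    def step(self, message):
        frame = self.get(message.keys[0])
        if self.curves is None:
            self.curves = [TuningCurve8() for _ in range(frame.shape[0])]
            keys = self.store.topic_entries("events")
            self.events = self.get(keys[-1]) if keys else []
        self.buffer.append(frame)
        t = len(self.buffer)
        while (
            self.next_event < len(self.events)
            and self.events[self.next_event].onset_frame
            + self.events[self.next_event].moving_frames <= t
        ):
            ev = self.events[self.next_event]
            trace = np.asarray(self.buffer).T  # (n, t)
            for i, c in enumerate(self.curves):
                update_direction_tuning(trace[i], ev, c, log=self.log)
            self.next_event += 1
        if self.curves and self.phase.phase == "characterization":
            complete = np.mean(
                [np.all(c.trial_counts > 0) for c in self.curves]
            )
            phase_controller(self.phase, float(complete), log=self.log)
            if self.phase.phase == "photostimulation":
                colors = [tuning_to_color(c) for c in self.curves]
                self.emit_payload(
                    "characterization",
                    {"curves": self.curves, "colors": colors},
                )


class PhotostimActor(Actor):
    def setup(self):
        self.n_targets = int(self.params.get("n_targets", 3))
        self.seed = int(self.params.get("seed", 0))
        self.events_out = []
        self.responses = []
        self.targets = []

    def step(self, message):
        payload = self.get(message.keys[0])
        curves = payload["curves"]
        n = len(curves)
        oracle, truth = synthetic.gen_photostim_network(n, seed=self.seed)
        rng = np.random.default_rng(self.seed)
        stimulated: set[int] = set()
        for _ in range(self.n_targets):
            try:
                tid = select_photostim_target(
                    truth.records, exclusions=stimulated, rng=rng
                )
            except Exception:
                break
            target = truth.records[tid]
            events, resp = run_photostim_protocol(
                target, response_oracle=oracle,
                repetitions=int(self.params.get("repetitions", 5)),
            )
            stimulated.add(tid)
            self.targets.append(tid)
            self.events_out.extend(events)
            self.responses.append(resp.mean(axis=0))
        self.truth = truth

    def teardown(self):
        out = _out_dir(self)
        if not out or not self.events_out:
            return
        with open(os.path.join(out, "photostim_events.jsonl"), "w") as fh:
            for ev in self.events_out:
                fh.write(json.dumps(ev.to_record()) + "\n")
        peaks = {
            r.id: float(self.truth.peak_directions[r.id])
            for r in self.truth.records
        }
        curves, counts = compute_photostim_tuning(
            self.targets, np.asarray(self.responses), peaks
        )
        _save_csv(
            os.path.join(out, "photostim_tuning.csv"),
            ["neuron"] + [f"dir_{d}" for d in range(0, 360, 45)],
            [(i, *["" if np.isnan(v) else float(v) for v in curves[i]])
             for i in range(curves.shape[0])],
        )


# --------------------------------------------------------------------------
# plumbing actors for property/fault tests and demos
# --------------------------------------------------------------------------

class FaultInjector(Actor):
    """Passes messages through, raising at a configured step index."""

    def setup(self):
        self.fail_at = int(self.params.get("fail_at", -1))
        self.count = 0

    def step(self, message):
        if self.count == self.fail_at:
            raise RuntimeError(f"injected fault at step {self.count}")
        self.count += 1
        self.emit(list(message.keys))


class CountingSink(Actor):
    def setup(self):
        self.received = []

    def step(self, message):
        self.received.append(message.keys)
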