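# neuroloop

Streaming analysis and closed-loop experiment design for neuroscience, built
on an actor-model pipeline framework.

Modern experiments stream data faster than offline analysis can keep up:
two-photon calcium movies, behavioral video, and electrophysiology arrive
frame by frame, and adaptive designs — pick the next stimulus, pick the next
photostimulation target — need models that are fitted *while* the data
arrive. `neuroloop` provides both halves:

* **Orchestration** — an actor framework in which each processing step is an
  isolated actor; actors exchange only *keys* into a shared in-memory store
  (payloads are stored once, however many consumers read them), queues are
  bounded with drop-oldest overflow so the pipeline stays current, and a
  fault in one actor never halts the rest of the run. Pipelines — including
  cyclic, closed-loop ones — are declared in plain YAML files.
* **Streaming estimators** —
  - *proSVD*: incremental top-k SVD with orthogonal-Procrustes alignment to
    the previous basis, so the learned subspace is stable enough for
    downstream regressors;
  - *streaming ridge regression*: running sufficient statistics `X^T X` and
    `X^T Y`; coefficients after every sample equal the batch ridge fit on
    that prefix;
  - *linear-nonlinear-Poisson (LNP) population model*: per neuron *i*,

    ```
    y_i(t) ~ Poisson(λ_i(t)),
    λ_i(t) = exp( b_i + K_i·s_t + Σ_l H_il y_i(t−l) + Σ_j W_ij y_j(t−1) )
    ```

    with an 8-direction stimulus term, a 4-frame self-history filter, and
    pairwise functional coupling `W` (zero diagonal), fitted by windowed
    stochastic gradient ascent on the Poisson log-likelihood;
  - *Bubblewrap*: a streaming Gaussian-mixture hidden-Markov model that
    tiles the latent space with N Gaussian "bubbles", filters the tile
    occupancy, and learns a row-stochastic transition matrix `A` online;
    `α^T A^k` gives k-step-ahead predictive mixtures scored by log
    predictive probability and transition entropy.
* **Closed-loop design** — exact GP regression of binocular tuning surfaces
  on a 24×24 toroidal stimulus grid (one motion angle per eye, 15°
  steps, squared-exponential kernel on the wrap-around distance),
  upper-confidence-bound stimulus selection `argmax f + κσ`,
  expected-improvement stopping, population-shared response histories, and
  opsin/tuning-based photostimulation target selection with a timed
  repetition protocol.
* **Synthetic data** — generators with ground truth for every stage:
  calcium movies with known ROIs and spikes, tuning surfaces with known
  peaks, LNP populations with known coupling, low-rank behavior/neural
  stream pairs, noisy limit cycles, and photostimulation networks.

## Worked example

Run the packaged closed-loop stimulus-optimization demo (a cyclic pipeline:
a stimulus presenter actor feeds population responses to a Bayesian
optimization actor, which feeds stimulus commands back):

```bash
neuroloop demo fig5_bo --scale small --seed 0 --out out/fig5
```

prints

```
BO peak recovery: 96.7% of 30 neurons within 1 grid step
run complete: 7 log events, 0 faults; outputs in out/fig5
```

Each of the 30 simulated neurons has a wrapped-Gaussian tuning surface on
the 24×24 torus with trial noise of 0.2× its amplitude. The loop starts
from 8 whole-field stimuli, then per neuron selects stimuli by UCB until
expected improvement drops below 1e-2 (at most 30 stimuli per neuron,
responses shared across the whole population). "96.7% within 1 grid step"
means that for 29 of 30 neurons the argmax of the online GP fit lies within
one 15° step (circular distance) of the true tuning peak.
`out/fig5/bo_trace.csv` lists, per neuron, the stimuli spent, the estimated
peak, and its distance to the truth; `runlog.jsonl` is the structured event
log of the pipeline run.

Other demos: `fig2_lnp` (streaming LNP fitting with functional-connectivity
recovery), `fig3_behavior` (video → proSVD → ridge, with the regression map
projected back onto pixels), `fig4_bubblewrap` (trajectory prediction with
per-horizon log predictive probability), `fig6_photostim` (visual
characterization phase that automatically switches to adaptive
photostimulation). `neuroloop validate <cfg>` checks any pipeline config;
`neuroloop run <cfg>` executes it.

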