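# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `neuroloop`. Empirical statements here are limited to what
the test suite and `scripts/acceptance.py` themselves compute.

## Orchestration

Actors are the unit of isolation: each owns no shared mutable state except
the central key-addressed store, and all coordination is by message
passing. A message carries only `DataKey`s; the payload lives in the store
exactly once regardless of the number of consumers. Two executors satisfy
the same observable contract (per-edge FIFO delivery, fault containment,
end-of-stream propagation): a threaded executor (one thread per actor, the
deployment mode) and a deterministic cooperative round-robin executor used
by the property tests, where reproducibility matters more than parallelism.

Queueing policy: bounded FIFO edges (default capacity 256). On overflow the
*oldest* data message is dropped and logged — a live system should stay
current rather than complete. Control messages (end-of-stream) are never
dropped. Store retention keeps the newest 200 entries per topic by default;
the newest entry of a topic is never evicted, even under a byte budget.
Faults inside an actor's `step` mark it failed, seal its input queues
(subsequent sends are dropped with a log event), propagate end-of-stream
downstream, and leave every other actor running; faults during `setup`
abort the run before it starts. Timestamps come from a monotonic clock;
wall-clock time is recorded separately in the run log.

Graph validation permits cycles — closed-loop designs are cyclic by
construction — but requires every weakly connected component to contain a
source: either a node with no inbound edges or one whose implementation
declares `is_source = True` (a data acquirer sitting inside a feedback
loop). A cooperative run in which only mutually waiting actors remain is
detected as a stall and terminated cleanly rather than spinning.

## Preprocessing

Otsu binarization (maximal between-class variance; pixels strictly above
threshold are foreground) and the Sørensen–Dice coefficient
`2|X∩Y|/(|X|+|Y|)` drive imaging-plane alignment: each candidate plane in a
five-plane stack (±6, ±3, 0 µm) is binarized and scored against the
binarized reference image; ties prefer the smallest |offset|, then the
lower index. Both-empty masks score 1 by convention.

Spike binning uses half-open bins `[kw, (k+1)w)` — an event exactly on a
boundary belongs to the upper bin. Rate smoothing convolves with a
truncated Gaussian kernel of 50-bin window, normalized to unit sum, with
reflect padding; the kernel's σ defaults to window/10 = 5 bins
(configurable — the window length is the externally fixed quantity, σ is
not).

Direction tuning: a trial's response is the mean over 15 frames from
stimulus onset minus the mean over the 10 frames directly before onset
(the onset frame belongs to the response window only); per-direction
running means are updated trial by trial and equal the batch means exactly.
The hue wheel for the color code fixes forward motion (0°) at green and
interpolates hue around the HSV circle by the rectified-response circular
mean; brightness is the peak response normalized by a population maximum.
This mapping is a convention — only "forward = green hues" is externally
fixed.

ROI trace extraction is deliberately simple — the mean intensity over a
known footprint, no motion correction, no source extraction, no
deconvolution. Real experiments put an online source-extraction algorithm
in that slot; here the synthetic movies provide ground-truth masks, and
spike counts for model fitting come from the generators.

## Streaming models

**proSVD.** State is an orthonormal basis `Q (d×k)` plus a `k×k`
carrier `B` of the singular-value structure. A new column is split into
its in-span coefficients and residual; the `(k+1)×(k+1)` augmented system
is decomposed, truncated to rank k, and the new basis is rotated by the
orthogonal Procrustes solution onto the previous `Q`, so basis vectors
move only as much as the subspace itself moves. Right singular rotations
are discarded (they do not affect the left subspace or later updates). A
residual below 1e-10 (relative) takes a rank-preserving in-span update that
leaves `Q` unchanged up to numerical precision. Initialization requires a
block of at least k columns with full rank k.

**Streaming ridge.** `G += x x^T`, `C += x y^T`; coefficients solve
`(G + λI)β = C` by a symmetric positive-definite solve. λ defaults to
1e-5 and is fixed per run. This is exactly single-pass: each datum is seen
once, and the coefficients equal the batch ridge fit on every prefix (the
module's exactness anchor, asserted at 1e-8). Coefficient maps are
projected back to pixels as `Qβ` and normalized to the top coefficient.

**LNP.** The model and window are described in the README. Numerical
choices: the linear drive is clipped at 30 before exponentiation (rates
saturate at e^30); the Poisson log-likelihood drops the `log y!` constant;
the coupling diagonal is re-zeroed after every update; a non-finite
gradient skips the step with a log event rather than corrupting state. The
ring buffer holds the window (10–100 frames, default 100) plus 4 frames of
history context; frames before the stream start count as silent.
`lnp_sgd_step` is the plain constant-step ascent (default 1e-5).
`LNPFitter` defaults to Adagrad per-parameter step scaling (base 0.01):
the baseline, stimulus, history, and coupling blocks have very different
curvatures, and a single constant step that is safe for the coupling block
under-drives the rest; per-parameter normalization is the package's
"step size chosen from the data". `lnp_fit_offline` (L-BFGS on the same
objective over the full data) is the reference the streaming fit is
benchmarked against.

**Bubblewrap.** N = 50 Gaussian tiles (default), forgetting λ = 1e-3,
prior strength ν = 1e-3, transition step η = 8e-3, initialized from the
first 20 points (means on/near the points with 10% jitter for N > points,
covariances at the data scale, uniform `A` and `α`). Per point: (1) the
one-step predictive density `Σ_j (α^T A)_j N(x; μ_j, Σ_j)` is evaluated
*before* any update; (2) the HMM filter updates `α`; (3) tile sufficient
statistics decay by (1−λ) and absorb the responsibility-weighted point,
with a prior of strength ν toward the initial data scale and a covariance
eigenvalue floor at 1e-6 of the data variance (keeps every Σ positive
definite); (4) `A` takes an EM-style convex step of size η·α_i per row
toward the posterior transition responsibilities — this keeps rows exactly
stochastic, unlike a projected additive gradient, while increasing
predictive likelihood for small steps; (5) a tile whose exponentially
averaged responsibility over the last 500 steps falls below 1e-4 is
teleported onto the latest observation with a doubled-scale covariance (at
most one tile per step, logged). Transition entropy is the
occupancy-weighted mean row entropy of `A` in bits. The horizon-k
prediction propagates `α` through `A^k`; its components are the current
tiles, so long-horizon scores reflect both transition diffusion and tile
placement.

The `workflows.latent_horizon_prediction` pipeline chains 10 ms binning,
50-bin smoothing, proSVD to 6 dimensions (initialized on the first 100
timepoints), and Bubblewrap, reporting per-horizon means over the second
half of the stream — the configuration used for electrophysiology-style
latent trajectory prediction.

## Closed-loop design

**GP on the torus.** Grid coordinates are normalized to [0,1) with spacing
1/24, distances wrap per axis, and the kernel is squared-exponential with
default length scale 3/24 (three grid steps; surfaces of width 2–4 grid
steps are well matched by this choice). The posterior over all 576 points
is exact GP regression; repeated observations at one grid point are
collapsed to their mean with noise variance σ²/n, which is algebraically
identical to the dense system (asserted against a dense-solve oracle at
1e-8). Zero observation noise with repeated points is rejected with a hint
to set a noise floor.

Response units are arbitrary, so the kernel is rescaled per neuron from its
own observation history: noise variance = 1.0 × the observed response
variance (deliberately conservative — over-smoothing is cheaper than
chasing trial noise), signal variance = the squared half-range of the
observed responses. The signal collapse is gated on grid coverage: until
the presented stimuli cover the grid to within twice the kernel length
scale, a flat history is indistinguishable from an unluckily sampled narrow
bump, and the prior keeps unit scale to drive exploration. After coverage,
a genuinely flat neuron's prior collapses and the expected-improvement stop
fires quickly.

**The loop.** Eight whole-field stimuli at 45° spacing (random order) seed
the very first neuron; thereafter every presentation's responses are
recorded for *all* neurons, so later neurons start with a full history.
Per neuron: select by UCB `argmax f + κσ` (κ default 0.5 — once the grid
is covered by shared history, exploitative sampling near the estimated
peak is what refines its localization; ties go to the lowest linear index;
a candidate already sampled more than 5 times falls back to a uniformly
random grid point, generator seeded 1337), present, refit, and evaluate
the stop: maximum expected improvement against the best observed mean
response below 1e-2, evaluated only after the neuron's own loop has
presented at least 3 stimuli (stopping is checked after a presentation, and
a neuron is never scored purely on hand-me-down data). A neuron that hits
the 30-stimulus cap un-converged is re-queued once, after the rest of the
population. Peak estimates are the argmax of the final posterior mean;
distances on the torus use per-axis wrap-around.

**Photostimulation.** Candidate targets must lie in the central x-range
(−75, 75), score positively in the inner product of their tuning color
[r, g, b] with a criteria basis (default [−1, 1, −1]: select green/forward,
reject red and blue), and exceed a summed red-channel opsin intensity of
50. Selection takes either the maximum-intensity candidate or a random
above-threshold one (mode flag); already-stimulated neurons are avoided
with probability 0.9 but not absolutely. The protocol emits 5 repetitions
spaced 15 s apart (duration 200–300 ms, 1 ms dwell) and collects per-neuron
responses, reusing the 15-frame-response/10-frame-baseline windows from the
visual analysis. Photostimulation tuning curves group events by the
target's visual peak direction and average within each of the 8 bins.
The experiment phase switches one-way from characterization to
photostimulation when ≥ 90% of tracked neurons have at least one trial in
all 8 directions; the 90% criterion is a package convention. The pipeline
ends at emitting target coordinates plus spiral parameters — galvo
waveform synthesis belongs to the rig.

## Synthetic data: what it does and does not emulate

Generators are deterministic under a seed and return the latent truth
needed to score every estimator. Conditions emulated: Poisson spiking with
exponential-decay calcium kernels (τ = 7 frames at 3.6 Hz, slow-indicator
like); interleaved stationary/moving gratings (5.3 s / 4.2 s at 3.6 Hz,
giving the 15-frame response window); wrapped-Gaussian binocular tuning of
width 2–4 grid steps with trial noise 0.2 × amplitude (this noise level
yields single-neuron stimulus budgets in the high single digits to low
tens); LNP populations with coupling at 20% rate modulation per presynaptic
spike (spectral radius of |W| kept below 0.9 for stability — and chosen so
that coupling is identifiable from 5,000 frames, the premise of a recovery
study); low-rank behavior video (localized Gaussian blobs × slow
oscillations); harmonic limit cycles under Gaussian noise; and a
latent-cycle-driven spiking population (30 units, 5–20 Hz, 1 s period —
one period per 100 bins at 10 ms) standing in for motor-cortex reach data.

Not emulated: motion artifacts and drift in movies beyond rigid shifts,
overlapping/shared-pixel ROIs, indicator nonlinearity and saturation,
non-Poisson spiking statistics, behavior-video realism beyond low-rank
structure, non-stationary tuning. Passing tests therefore demonstrate
algorithmic correctness and closed-loop behavior under the stated
statistical assumptions, not robustness to the full messiness of in vivo
data.

## Known limitations

* Single centralized store and supervisor; no multi-machine distribution,
  no hot code swap, no store persistence beyond JSON/CSV dumps.
* The cooperative executor is single-threaded by design; the threaded
  executor's throughput is bounded by the interpreter lock, which is
  adequate for the desk-scale demos but not a real acquisition rate
  benchmark.
* Bubblewrap's transition update is an online EM convex step rather than a
  raw additive gradient; this trades a slightly different step geometry for
  exact row-stochasticity at every step.
* GP hyperparameters (length scale, κ) are fixed per run, not learned
  online; the per-neuron rescaling covers amplitude units only.
* The LNP uses generator spike counts directly; with real fluorescence a
  deconvolution stage would precede it.
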