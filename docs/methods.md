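# Methods

This note records the models, numerical choices, and design decisions
behind `superstat`, and what the packaged synthetic benchmarks do and do
not establish.

## Model family

A superstatistical model layers two stochastic processes. The low-level
(observation) model generates one data point per trial from the current
parameter vector ``θ_t``; the high-level (transition) model describes how
``θ_t`` evolves, governed by static hyperparameters ``η``. The initial
``θ_0`` and ``η`` carry priors. Inference targets the filtering posterior
``p(θ_t, η | x_{1:t})`` for every ``t`` — beliefs about the current
parameters and the transition law given the data so far.

### Observation models

**Poisson counts.** One non-negative integer per step with rate ``λ_t``
(events/step). The log-likelihood is evaluated in closed form.

**Diffusion decision model (DDM).** Two-choice trials described by a
drifting evidence accumulator with unit diffusion coefficient: drift ``v``
(evidence/s, one per stimulus condition when several conditions are
declared), boundary separation ``a`` (evidence units), non-decision time
``τ`` (s). The start point is fixed at ``a/2`` (unbiased). Parameters per
trial come from the trajectory row of that trial; multi-condition designs
draw the trial's condition uniformly at random, mirroring randomized
stimulus schedules.

### Transition models and priors

Transitions act on an *unconstrained* scale: ``a`` and ``τ`` are
log-transformed, so Gaussian increments can never produce invalid
parameters, and drifts are untransformed. The one deliberate exception is
the Poisson rate: its random walk acts on the natural ``λ`` scale with a
small positive floor (1e-3), because the lattice filter — the independent
oracle for this model — propagates a Gaussian kernel in rate units, and the
neural and lattice methods must target the *same* generative model for
their comparison to be meaningful.

Defaults (all overridable in the model config):

| quantity | prior / value | rationale |
|---|---|---|
| ``λ_0`` | Exp(rate 0.5), mean 2 | informative prior of the count benchmark |
| random-walk scale ``σ`` (all parameters) | Beta(1, 25), mean 0.038 | favors slow drift; a series of a few hundred trials accumulates O(0.4–0.8) of total movement |
| ``v_0`` per condition | Normal(0, 2.5) | wide enough for near-chance through near-ceiling accuracy |
| ``a_0`` | Gamma(4, rate 3), mean 1.33 | typical thresholds ~0.8–2.5 |
| ``τ_0`` | Gamma(1.5, rate 5), mean 0.3 s | typical non-decision times 0.1–0.6 s |
| GP amplitude / length-scale | Exp(4) / U(0.05, 0.5) | total variation comparable to the random walk; smooth paths over the [0,1]-normalized trial grid |
| regime-switch jumps | U(−4,4) for ``v``, U(0.5,3) for ``a``, U(0.1,1) for ``τ`` at trials {100, 200, 300} | piecewise-constant stress test |
| hard support | ``a ∈ (0.001, 10]``, ``τ ∈ (0.001, 5]`` s | thresholds or non-decision times beyond these are outside any plausible two-choice experiment, and keep simulated trials inside the 10 s budget |

The GP time grid is normalized to [0, 1] so length-scales are comparable
across series lengths; sampling uses a Cholesky factor with 1e-6 diagonal
jitter, independently per parameter, and the simulator conditions the path
on its ``θ_0`` prior draw at t = 0. Each simulated record splits its seed
into prior / transition / observation substreams, so observation noise is
reproducible independently of trajectory noise.

## DDM first-passage simulation

Trials are integrated by Euler–Maruyama with ``dt = 1 ms`` (configurable)
up to ``t_max = 10 s``. A naive end-of-step boundary check overestimates
first-passage times by O(√dt) — enough to be detectable against the
closed-form mean decision time at 10⁴ trials — so each step additionally
applies the standard Brownian-bridge test for an unobserved within-step
crossing, which removes the leading-order bias. Trials that never cross are
flagged as timeouts and *retained* (silently resampling them would bias the
tails); under the default static priors the timeout rate is ~0.02%.

The analytic cross-check is the Wiener first-passage-time density,
evaluated by the small-time/large-time series expansions with the
truncation order chosen adaptively for ≤1e-6 absolute error; the upper
boundary density is obtained by reflection. For the symmetric start point
the choice probability ``1/(1+e^{−va})`` and mean decision time
``(a/2v)·tanh(va/2)`` provide elementary oracles.

## Lattice filter

The Poisson + random-walk model is low-dimensional enough for exact
filtering on a grid: 200 equally spaced rate points on [0, 15] and 40 scale
points on [0, 1] by default (a 4000-point rate lattice matches the
benchmark resolution and is a config choice away). Each predict step
convolves the probability mass with a discrete Gaussian kernel; mass
leaving the lattice is truncated and the rest renormalized (reflection
would distort mass near 0). Kernels are variance-matched at every
resolution: density sampling when ``σ ≥ 2h`` (spectrally exact), CDF
differences with a bin-width variance correction for ``h < σ < 2h``, and a
three-point kernel with exact second moment for ``σ ≤ h``. Updates multiply
by the Poisson likelihood in log space with max-shift normalization; the
log normalizer increments the evidence. The σ lattice carries one filter
per point; the filtering mean/SD of ``λ_t`` reported at step t marginalizes
over σ with weights ∝ prior(σ) · evidence(σ | x₁:ₜ).

With σ = 0 the filter must reproduce conjugate Gamma–Poisson updating; the
test suite pins means and SDs to the closed form at 0.5% and the evidence
to chunking invariance. Note the exact posterior SD is *not* monotone in t:
a large count can raise ``√(1+Σx)/(0.5+t)``; the filter reproduces this.

## Amortized neural filter

**Summary network.** A single LSTM layer (width 64 for the DDM, 128 for the
Poisson benchmark) consumes one feature vector per trial; its hidden state
``h_t`` is a causal summary of ``x_{1:t}``. Count series are encoded as the
standardized count. DDM series are encoded per trial as (log rt, rt,
choice ∈ {−1, +1}, one-hot condition when multi-condition) plus two causal
prefix statistics: the expanding minimum and a 20-trial rolling minimum of
rt. The minimum rt is the near-sufficient statistic for the non-decision
time, and supplying it directly (rather than hoping the recurrence learns a
running minimum) roughly halves the benchmark's τ recovery error at equal
training cost. All features are z-scored with constants estimated from a
pilot simulation and frozen into the checkpoint.

**Posterior heads.** The joint posterior is factorized ancestrally:
``q(η | h_t)`` then ``q(θ_t | h_t, η)``. The default head is a conditional
Gaussian whose conditioner predicts the mean and a lower-triangular
*precision* factor A (positive diagonal via a bounded log-diagonal), so the
log-density needs no matrix inversion and sampling solves one triangular
system. A conditional affine-coupling normalizing flow (4 blocks,
alternating masks, tanh-bounded log-scales) is available for multimodal or
skewed targets; the packaged DDM benchmarks default to the Gaussian head
because on the transformed (log) scale the filtering posteriors at these
problem sizes are close to Gaussian and the head trains several times
faster on one CPU. Targets are learned on the standardized unconstrained
scale (log for positive quantities, including all scale-type η components);
draws are back-transformed and clipped to the declared support.

**Training.** The criterion is the expected negative log posterior density
of the true simulated parameters, summed over all time steps and averaged
over simulated records. Because the term at time t conditions only on the
prefix ``x_{1:t}``, training on sequences of length T simultaneously trains
the filter for every shorter series — the packaged DDM network trains on
T = 300 and serves any T ≤ 300 without extrapolation. Optimization uses
Adam (cosine-decayed learning rate, global-norm gradient clipping at 5) on
an offline store of simulated records (online regeneration per epoch is
available). The whole stack runs in float32 on a minimal in-repo
reverse-mode autodiff engine; every op and the end-to-end LSTM+head
gradients are finite-difference-checked in the tests.

Benchmark budgets (package choices, configurable): Poisson — 5120
simulated series of T = 110, 30 epochs, batch 128; DDM — 3072 series of
T = 300, 16 epochs, batch 256. Each trains in minutes on a single CPU.

**Inference.** One LSTM pass plus vectorized head sampling yields n joint
draws of (θ_t, η) for every t; runtime is linear in T and sub-second for
hundreds of trials.

## Validation workflow and operationalizations

- **SBC**: ranks of the true parameter among n posterior draws across many
  simulated data sets must be uniform. Uniformity is assessed by a KS test
  on the (jitter-free) normalized ranks *and* by a simultaneous 99% ECDF
  band calibrated by Monte Carlo from the uniform null; "gross
  miscalibration" is operationalized as more than 10% of ECDF evaluation
  points outside the band. The exactly calibrated conjugate sampler (σ = 0
  Poisson) is the positive control; the same sampler shifted by +0.5 is the
  negative control.
- **Recovery**: MAE(t) is the median over records of |truth − posterior
  mean| (per parameter), posterior SD(t) the median with a MAD band, plus
  truth-vs-mean scatter and Pearson correlation at chosen trials.
- **Pseudo-dynamics**: when the generator is static, the *across-fits mean*
  of the posterior-mean trajectories is compared to the median marginal
  posterior SD. The averaging isolates systematic temporal artifacts: the
  per-series wobble of any filter under a random-walk prior is
  Bayes-optimal behavior, not an artifact — the exact lattice filter shows
  per-series wobble around 40% of its posterior SD under the default scale
  prior — whereas artifacts common to all fits survive averaging.
- **Retrodiction / multi-horizon prediction**: re-simulated series use one
  posterior draw index per replicate (trial-wise θ draws for the observed
  span; a fresh transition trajectory seeded at the θ draw with its matched
  η for the future span). Bands are equal-tailed 95% intervals of the
  simulated series, smoothed — like the data — by a trailing
  simple moving average (period 5; the first period−1 entries average the
  available prefix so lengths match). A held-out series counts as
  "contained" when at least 90% of its smoothed points fall inside the
  band.
- **MMD**: unbiased U-statistic with a Gaussian kernel, bandwidth from the
  median heuristic on the pooled sample, clipped at 0; checked against a
  brute-force double loop.

## What the synthetic benchmarks do and do not show

The generators emulate trial-wise RT/choice or count series up to a few
thousand trials with smoothly drifting (or abruptly switching) parameters,
under the priors above. Passing benchmarks establishes that the amortized
filter matches an exact oracle where one exists, is calibrated in the SBC
sense on data *from the assumed model family*, recovers drifting parameters
it was trained to see, and does not invent dynamics on static data. Real
response-time data differ in ways the generators do not model: contaminant
responses and lapses, post-error slowing, parameter dynamics tied to the
stimulus sequence, serial dependence in conditions, and any
misspecification of the DDM itself. Performance on such data must be
assessed with the retrodictive and predictive checks, not inferred from
these simulations.

## Known limitations

- The Gaussian head cannot represent multimodal filtering posteriors
  (e.g., shortly after an undetected regime switch); the flow head exists
  for that case but is slower to train.
- Non-decision time posteriors are the most delicate: τ is bounded above by
  the smallest observed rt, making its posterior skewed when data are few.
  Mild τ miscalibration in SBC is the expected failure mode and is
  surfaced, not suppressed, by the ECDF diagnostics.
- The lattice filter is restricted to one low-level dimension by design;
  its cost grows exponentially with dimensions, which is precisely the
  regime the neural filter exists for.
- Training budgets are deliberately desk-scale; the reported benchmark
  numbers are expected to tighten (not change qualitatively) with larger
  simulation budgets and wider networks.
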