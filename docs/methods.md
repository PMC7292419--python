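# Methods

## The generative model of the task

A session is a sequence of `n_trials = 380` binary tones.  The pair of
transition probabilities θ = (p(A|A), p(B|B)) is piecewise constant: on every
trial after the first, a change point occurs with probability
`p_change = 1/75`, in which case both probabilities are redrawn
independently and uniformly from `[resample_low, resample_high] = [0.1, 0.9]`,
rejected until

|log odds(θ_new) − log odds(θ_old)| ≥ log 4

for at least one of the two probabilities (rejection is capped at 10⁴ draws
and raises on infeasible configurations; at the default bounds acceptance is
common).  The first tone is equiprobable; every later tone is drawn from the
transition probability conditioned on its predecessor.  Segment lengths are
therefore geometric with mean 75 trials, which the test suite checks by a
χ² goodness-of-fit.

Probe questions interleave the tone stream.  Only the gap median (13) and SD
(4.4) of the schedule are constrained; we draw gaps as `round(N(13, 4.4))`
redrawn below 2 trials.  Questions do not interrupt the tone sequence or the
observer's updating — the sequence the observer sees is contiguous, and the
schedule is only used to subsample trials (e.g. for report simulation and
decoding).

A cohort is `n_subjects = 24` × `n_sessions = 4` independent sessions.  One
master seed spawns per-subject and per-session child seeds
(`numpy.random.SeedSequence.spawn`), so any subset of the cohort is
reproducible in isolation and reruns are bit-identical.

## The ideal observer

The observer knows the generative model, including `p_change`, but not the
resampling bounds or the fold-change constraint: its change-point kernel
resamples both probabilities jointly from a flat prior over the full unit
square.  Inference is a hidden-Markov forward recursion over a discretized
joint grid of `grid_n × grid_n = 20 × 20` cells.  Grid values are the
midpoints `(i − 0.5)/grid_n`, which exclude 0 and 1 so that likelihoods are
never zero and surprise is always finite.  One step is:

1. transition: `b ← (1 − p_c)·b + p_c·uniform` (mass-preserving mixture);
2. likelihood: multiply by `p(y_t | y_t−1, θ)` cell-wise;
3. renormalize.

Arithmetic is linear-domain with per-step renormalization; because the
transition kernel mixes in a constant floor `p_c / grid_n²`, the posterior
never underflows at the required scales (10⁶ simulated trials are checked
for finiteness in the suite).  The forward pass is validated against an
independent oracle that enumerates all 2^(n−1) change-point configurations
of short sequences (agreement < 1e-10 per cell), and against conjugate
Beta-on-the-grid counting in the `p_change = 0` limit (1e-12).

### Per-trial latent variables

All "predictive" quantities at trial t condition on the tone at t − 1 and
are computed from the posterior carried over from trial t − 1 — not from the
belief after a further application of the change-point kernel.  This is the
literal reading of the definitions (mean and log-precision of
p(θ_t | y_1:t)); the kernel's effect on the next trial's belief is small
(order p_c), but the choice matters for the confidence statistics, since the
kernel imposes a variance floor that compresses high confidence.

- prediction: mean of the relevant marginal, mapped to P(next = A)
  (`E[θ_AA]` after an A, `1 − E[θ_BB]` after a B);
- surprise: `−log₂` of the probability assigned to the observed tone (bits);
- confidence: `−log` (natural) of the relevant marginal's variance;
- belief update: `KL(posterior_t ‖ reference)` in nats.  The reference is,
  by default, the *post-transition* belief — what the observer holds just
  before the likelihood, i.e. the previous posterior passed through the
  change-point kernel.  The alternative reading (the previous trial's raw
  posterior) is available as `kl_prior="pre_transition"`; it adds the
  volatility leak itself to every update and raises the update-regression
  ρ from 0.85 to 0.88.

Trial 1 has no predecessor: prediction is fixed at 0.5, surprise is 1 bit,
confidence and update are NaN, and the trial is flagged and excluded from
all regressions.

## Derived statistics and their conventions

All regressions include an intercept and z-scored predictors.  Two
conventions required explicit decisions; both are exposed as options and the
defaults are stated here.

**U-shape of confidence in the prediction.**  The naive design
`conf ~ z(p) + z(p²)` is nearly singular — corr(z(p), z(p²)) ≈ 0.97 on these
traces — which makes the p² weight huge and unstable (≈ 2.9 ± 0.10 across
simulated subjects).  The default therefore uses the *centered square*, the
square of the z-scored prediction, i.e. the squared deviation of p from its
mean.  This regressor is nearly orthogonal to p, isolates curvature, and
yields a stable group weight of ≈ 0.60 ± 0.02 (z-scored outcome).  Set
`center_square=False` for the raw square.

**History effects on confidence.**  The effects of the previous trial's
surprise and of the log number of observations since the last (generative)
change point are estimated, by default, on *residual confidence* — the
residuals of regressing confidence on [1, p, p², log p, log(1−p)] — in its
natural (log-precision) units, with the predictor z-scored.  Residualizing
removes the prediction-driven channel shared by all three effects, so the
history weights quantify precision dynamics proper; in natural units they
are directly comparable across the analyses that use residual confidence as
a regressor.  On the default cohort this gives −0.23 ± 0.01 (previous
surprise) and 0.17 ± 0.01 (log observation count).  Set
`residual_outcome_for_history=False` for z-scored raw confidence, which
yields much larger magnitudes (−0.64, 0.36) because raw confidence is
dominated by the prediction-coupled channel.

"Observations since the last change point" counts from the true generative
change points (known in simulation), 1-based within each segment.

**Update additivity.**  The KL update is regressed, pooled over all valid
trials of the cohort, on z-scored surprise and confidence (the fitted-vs-
actual Pearson ρ is invariant to the z-scoring scope).  On default cohorts
ρ ≈ 0.85 without and ≈ 0.88 with the interaction term.  The reference value
for the no-interaction regression is 0.836; our traces reproduce it within
±0.02 across master seeds.  The reference for the interaction variant
(0.839, i.e. a near-zero interaction contribution) is *not* reproduced: in
these traces the interaction consistently adds ≈ 0.03 of correlation under
every latent/KL convention we examined.  We report the measured value rather
than tune any convention to the target.

**Adjacent-trial correlation.**  Quoted for residual confidence (the slow
component relevant for trial-binning arguments): ≈ 0.61 within sessions.
Raw confidence is more autocorrelated (≈ 0.72) because the prediction-driven
component persists within segments.

## Synthetic signals

Power/ERF generator (per trial, CONF and SURP the z-scored confidence and
surprise; flagged trials enter at the mean):

    power_neural = β₁·CONF + η             η: AR(1), SD 1, lag-1 ρ 0.5
    erf_neural   = −(β₂·SURP − β₃·power_neural) + ε_erf
    power_meas   = power_neural + ε_common
    erf_meas     = erf_neural  − ε_common

with β₁ = 0.25, β₂ = 0.25, β₃ = 0.5 and unit-SD white ε noises.  The common
noise models trial-to-trial recording gain: a stronger recording inflates
measured power *and* deepens the (negative) evoked deflection, so the same
realization loads on the two measured signals with opposite signs, and the
spurious single-trial power→ERF coupling it creates opposes the true
positive β₃ coupling.  Averaging b consecutive trials shrinks the white
common noise variance by 1/b while the confidence-driven coupling (slow)
survives, so the group t of the power coefficient rises with bin size —
crossing from negative (artifact-dominated) to positive — and with
`sd_eps = 0` the regression recovers β₃ = 0.5 exactly at every bin size.
These couplings are illustrative defaults (only the structure matters), not
fits to data.

Pupil: tonic = −0.1·CONF + AR(1) noise with lag-1 autocorrelation 0.75;
phasic = +0.2·SURP + white noise; the gains are invented plumbing with only
their signs constrained, and 0.75 is the trial-to-trial autocorrelation
target for the tonic level.

Reports: a logistic squash of `r·CONF + √(1−r²)·noise` on question trials,
with `r` corrected for the squash's attenuation (computed by Gauss–Hermite
quadrature under a normal approximation to CONF) so that
corr(report, CONF) ≈ 0.23 by default.  The correction saturates at a
noiseless readout when the target exceeds the squash ceiling.

## Statistics

- Mass-univariate OLS fits every timepoint independently; t-values use the
  shared `(XᵀX)⁻¹` and per-timepoint residual variance.
- The 1-D cluster permutation test forms contiguous supra-threshold runs of
  the group one-sample t (threshold: two-tailed t-quantile of the
  cluster-forming p at n−1 df), scores them by summed t, and builds the null
  from `n_perm` random whole-subject sign flips using the maximal cluster
  mass; p = (#{null ≥ observed} + 1)/(n_perm + 1), so p > 0.  Sign flips
  leave per-subject squares unchanged, which the implementation exploits to
  vectorize the permuted t-values.  Simulated family-wise error under the
  null is 0.05 ± 0.02 (400 replications in the suite).
- The shuffle control pairs each subject's signal with regressors drawn from
  other subjects (truncated to the shorter series) to form per-subject
  Z-scores; a shared temporal profile survives in the null and is absorbed.
- Ridge decoding z-scores features across rows, assigns row i to fold
  i mod 20, and solves the penalized normal equations (penalty 0.01 on the
  slopes, unpenalized intercept) via scikit-learn's `Ridge`.

## Problem sizes and limitations

Default experiment sizes are the study conditions themselves (24 × 4 × 380
trials, 20 × 20 grid); a full cohort simulates in ~2 s and the complete test
suite in well under a minute, so nothing is scaled down.  The synthetic
signal generators emulate only the per-trial scalar structure the analyses
rely on — linear couplings, autocorrelated noise, one shared noise source —
not sensor geometry, time–frequency structure, eye blinks, or any
nonstationarity of real recordings; passing tests therefore validate the
*analysis machinery* and the model-internal statistics, not claims about
real neural data.  The observer implements the fixed-volatility transition
model only (no hierarchical inference of the change probability, no
item-frequency coding variants).
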