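# Methods

This document records the model underlying the simulator, the statistical
conventions of the analysis suite, the numerical choices, and the known
limitations. Units throughout: times in milliseconds (ms), angles in degrees,
probabilities and proportions in [0, 1].

## 1. The paradigm being simulated

The task is a handedness comparison of a reference shape and a rotated (and
possibly mirrored) working stimulus at angular disparities of 60, 120, or
180 degrees. Participants can solve each trial *internally* (mental rotation)
or with the *extended* strategy: holding arrow keys physically rotates the
working stimulus on screen. A session consists of an optional practice phase,
nine forced-strategy calibration blocks alternating internal and extended
(order i, e, i, e, i, e, i, e, i; 48 trials per block), and four free-choice
blocks. Every trial times out after 12,000 ms; a timeout is recorded as an
incorrect answer with a 12,000-ms RT.

Two yoking mechanisms calibrate extended performance to each participant's
own internal performance:

* **Speed yoking.** At the end of every internal block an ordinary
  least-squares slope of RT on angle is estimated from all correct internal
  trials accumulated so far. The on-screen rotation speed is set to the
  inverse of that slope (so rotating through an angle takes about as long as
  mentally rotating it), expressed per 20-ms update tick and capped at
  1000 deg/s (Experiment-1 mode) or 750 deg/s (Experiment-2 mode). A slope
  of 2 ms/degree therefore yields 10 degrees per tick. Slopes below a floor
  of 0.1 ms/degree are clamped to the floor before inversion.
* **Reliability yoking.** Before each extended block, two *unreliable*
  trials are added per error committed more in the preceding internal than
  in the preceding extended block. On an unreliable trial the rotation fails
  at the first key press and the participant must guess (correct with
  probability 0.5). Block 4 is special: two internal blocks precede it, so
  the mean accuracy of Blocks 1 and 3 is compared with Block 2, with error
  counts reconstructed as `round(48 * (1 - accuracy))`. Error deficits never
  remove unreliable trials (a symmetric variant exists behind a config flag,
  off by default). Before the choice section one final update is applied
  using Blocks 9 and 8, and each choice block carries that final count of
  unreliable slots (active only on trials where the extended strategy is
  actually used); the placement of unreliable slots within a block is
  uniform at random.

Experiment-2 mode additionally imposes a 511-ms *lockout*: rotation begins
only after a continuous key press of 511 ms, shifting every extended RT by
exactly that constant.

## 2. Generative participant model

Each simulated participant is parameterised by a `ParticipantProfile`:

| field      | meaning                                               |
|------------|-------------------------------------------------------|
| `a_int`    | internal RT intercept (ms)                            |
| `b_int`    | internal RT slope (ms per degree), > 0                |
| `sigma_rt` | Gaussian RT noise SD (ms), shared by both strategies  |
| `eps0_int`, `eps1_int` | internal error rate at 0 deg and per-degree increment; P(error) = clamp(eps0 + eps1 * angle, 0, 0.5) |
| `a_man`    | extended motor/decision intercept (ms)                |
| `eps_man`  | extended error probability on reliable trials         |
| `rt_bias`  | metacognitive bias added to the perceived RT difference (ms) |
| `policy`   | logistic strategy-choice weights                      |

Internal trials: `rt = a_int + b_int * angle + noise`, truncated to
(0, 12000]; a draw reaching the deadline is a timeout. Extended reliable
trials: `rt = lockout + angle / speed + a_man + noise` with `speed` the
current calibrated rotation speed in degrees/ms; rotation time is treated as
continuous (the 20-ms tick quantisation is not simulated, which keeps the
kinematic identities exact). Unreliable trials: `rt = lockout + a_man +
noise`, answer a fair coin flip.

Strategy choice in the free-choice blocks is a single logistic policy:

    P(extended) = logistic(beta0 + beta_rt * delta_rt_s + beta_acc * delta_acc
                           + beta_angle * angle + beta_stick * s_prev)

where `delta_rt_s` is the *perceived* internal-minus-extended RT difference
in seconds, `delta_acc` the realised accuracy difference of the final yoked
block pair (7 minus 8), `angle` the trial's angular disparity, and `s_prev`
is +1/-1 after an extended/internal trial (0 on the first choice trial).
The perceived RT difference is the participant's steady-state expected
difference implied by their own parameters under the final calibration (the
intercept gap minus the lockout, plus any speed-cap shortfall, evaluated at
the mean angle) plus the metacognitive bias `rt_bias`. Using the expectation
rather than one noisy block-pair realisation keeps the choice input
independent of the measurement noise in the analysed Block-7/8 difference;
a per-participant constant bias is the simplest structure consistent with
the strong observed correlation between judged and actual speed advantage.

### Scenario presets

The paper gives no distributional information about participant-level
intercepts and slopes, so the preset values below are labelled conventions,
chosen a priori to produce the qualitative population signatures of the two
experiments, not estimates fitted to data.

* `exp1` (speed-only calibration, cap 1000 deg/s, no lockout): internal
  intercept ~ N(1911, 250), extended intercept ~ N(1400, 150) — an
  intercept gap with mean 511 ms, heterogeneous across participants
  (SD ~292 ms); slope ~ lognormal(mean 4, SD 1.2) ms/deg; RT noise
  ~ N(400, 50) ms; internal errors eps0 = 0.02, eps1 ~ N(4e-4, 1e-4);
  extended error 0.05; metacognitive bias ~ N(0, 250) ms; policy
  beta_rt = 4 /s, beta_acc = 4, beta_angle = 0.003 /deg, beta_stick = 1.
  Large heterogeneous experienced speed advantages push strategy use toward
  the extremes (the Fig.-5f-style pattern).
* `exp2` (lockout 511 ms, cap 750 deg/s): identical except intercepts
  ~ N(1911, 30) and N(1400, 30), so the gap is nearly homogeneous at the
  lockout value and the experienced RT difference collapses to ~0; choices
  are then dominated by the metacognitive bias and strategy use is unimodal
  around one half.
* `noiseless`: deterministic error-free performers (slope 2 ms/deg,
  intercepts 1911/1400, all noise and error rates 0, indifferent policy) for
  exact kinematic identities.

Cohort sampling is deterministic given (seed, draw index); distributions
whose draws violate profile invariants are rejected and redrawn, so
configured moments are only approximate when truncation bites.

## 3. Statistical conventions

* **Bimodality coefficient.** BC = (g1^2 + 1) / (g2 + 3(n-1)^2 /
  ((n-2)(n-3))) with bias-corrected sample skewness g1 and excess kurtosis
  g2 (the SAS definitions); limits 1/3 (normal) and 5/9 (uniform); critical
  value 0.55. Requires n >= 4 and non-constant data.
* **Hartigan dip.** The classical iterative greatest-convex-minorant /
  least-concave-majorant algorithm, with ECDF deviations measured in count
  units and the final maximum halved; range [1/(2n), 0.25]; ties are handled
  directly on the weighted ECDF with no jittering (relevant because
  strategy-use proportions are multiples of 1/192). Note that the iterative
  algorithm — the statistic as defined by its published implementation and
  reference tables — retains envelope deviations from earlier, wider modal
  windows and is therefore *not* exactly the minimum over all unimodal
  hull fits; an exhaustive hull-fit search is a lower bound (this is checked
  by a property test). P-values are Monte-Carlo calibrated against
  Uniform(0, 1) null samples of the same size (seeded, default 2000 draws,
  add-one continuity correction), rather than interpolated from published
  tables.
* **Combined verdict.** Unimodal iff BC < 0.55 and the dip is
  non-significant (p > .05); bimodal iff BC > 0.55 and significant;
  otherwise ambiguous.
* **Equivalence.** Paired t plus a Bayesian estimate of the mean difference:
  Student-t likelihood y_i ~ t_nu(mu, sigma) with priors
  mu ~ N(mean(y), 1000 sd(y)), sigma ~ Uniform(sd(y)/1000, 1000 sd(y)),
  nu - 1 ~ Exponential(mean 29). The 95% highest-density interval of mu is
  compared with the ROPE (+/-200 ms for RT, +/-2 percentage points for
  accuracy): fully inside = practical equivalence, fully outside = real
  difference, otherwise inconclusive. Interval containment is inclusive at
  the ROPE bounds.
* **Power.** `power_hdi_in_rope` simulates replicate datasets of n
  differences from N(true_mean, sd), computes each replicate's 95% HDI, and
  reports the fraction of HDIs inside the ROPE.

## 4. Numerical choices

* The BEST posterior is sampled by Gibbs using the normal scale-mixture
  representation of the t distribution: conjugate gamma updates for latent
  per-observation precisions, a conjugate normal update for mu, a truncated
  inverse-gamma update for sigma^2 (inverse-CDF sampling within the uniform
  prior's range), and random-walk Metropolis on log(nu - 1). The sampler is
  vectorised across replicate datasets, which makes 1000-replicate power
  runs take seconds on one CPU.
* Power runs default to 1500 kept draws after 300 burn-in per replicate
  (single chain) — a deliberately reduced MCMC length whose residual HDI
  noise is small relative to the +/-0.07 acceptance tolerance (doubling the
  kept draws shifts the estimated power by less than the Monte-Carlo
  standard error). `scripts/acceptance.py` uses 10,000 replicates per target
  so that the binomial standard error of each reported proportion stays
  below 0.004; two of the power values sit within about 0.01 of their
  tolerance bounds, so replicate count, not MCMC length, dominates the
  reproduction error. Single-dataset
  HDIs (`hdi_mean_diff`) use 4 chains of 2500 kept draws after 500 burn-in
  and require split-Rhat <= 1.05, raising a diagnostic error otherwise.
  A fast normal-theory approximation (`method="normal"`,
  mean +/- t_crit * s / sqrt(n)) is available for coarse power grids.
* HDIs are minimal-width windows over sorted draws (`ceil(level * m)` draws
  included). With finite draws the estimator is slightly narrow; the
  coverage acceptance test therefore uses 4000 draws.
* OLS slopes and the use-on-delta regression are computed from centred
  cross-products; the repeated-measures angle ANOVA delegates to
  `pingouin.rm_anova` with Greenhouse-Geisser correction and generalized
  eta squared, and is verified against a hand-computed oracle in the tests.
* All randomness flows through `numpy.random.Generator` objects; per-stage
  seeds are derived from the master seed via `SeedSequence` and recorded in
  the run manifest (all derived seeds are below 2^31).

## 5. Analysis pipeline conventions

* Cleaning order: timeout coding first, then one (non-iterated) pass of
  per-participant 4-SD RT trial exclusion using the mean/SD computed after
  coding. Cleaning is idempotent.
* Participant exclusions: rotated in < 85% of trials of extended calibration
  blocks 2/4/6/8 combined (`low_rotation`); grand-mean RT outside the group
  mean +/- 2.5 group SD of per-participant grand means (`rt_outlier`);
  combined accuracy over internal blocks 1/3/5/7/9 below 80%
  (`low_accuracy`). The "below 80% in all internal blocks" criterion is read
  as combined accuracy across those blocks. Absolute-gap calibration-outlier
  thresholds are available but disabled by default.
* Delta sign convention: internal minus extended, everywhere (Block 7 minus
  Block 8; the regression of use on delta uses seconds).
* Extended-strategy use u = proportion of choice-block trials with any
  rotation key press; perseveration thresholds 0.90/0.95/1.0, non-strict
  comparisons by default.

## 6. Scope of the generator and limitations

* The generator produces the *statistical structure* the paradigm assumes,
  not a reproduction of the deposited human data; observed human effect
  sizes (e.g. a 511-ms mean RT difference with SD 687 ms) are not targets.
* The one-sided reliability yoking over noisy binomial error counts is a
  ratchet: it overshoots by one to two errors on average, so simulated
  cohorts end with extended accuracy a few percentage points *below*
  internal accuracy (the accuracy-equivalence HDI typically lands outside
  the +/-2% ROPE on simulated data, unlike in the reported human results).
  This is a property of the stated update rule interacting with our error
  model, and is left visible rather than patched.
* Unreliable trials are faster than reliable ones (no rotation phase), so
  cohorts with nonzero unreliable counts show a small positive residual
  Block-7-minus-8 RT difference (~50-100 ms) even under a matched lockout;
  the exact-zero identity holds for noiseless, error-free cohorts.
* Practice-phase learning, reinforcement-learning choice dynamics, stimulus
  rendering, rotation-direction behaviour, and questionnaire measures are
  out of scope. The Experiment-1 slope-update bug mentioned in the paper's
  footnote is deliberately not reproduced; the corrected update is always
  used.
* The exact rule generating unreliable trials during the free-choice blocks
  is not stated in the source material; carrying the final calibration count
  into each choice block is a documented convention.
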