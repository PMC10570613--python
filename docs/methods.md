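# Methods

## Data model and preprocessing

The unit of analysis is the trial: one participant judging whether a
pronoun-initial continuation sentence follows sensibly from a context
sentence written in a gender-fair form. Trials carry the design factors
(experiment, condition, pronoun gender, counterbalancing list, trial role),
the yes/no response, correctness and the reaction time in ms. Two
preprocessing rules feed the models:

* **Reaction-time set** — experimental trials with a *yes* response only.
  Fillers never enter either model (the models carry item intercepts for the
  experimental words only).
* **Standardization** — RTs are z-scored, pooled over all retained trials
  within an experiment. Pooling (rather than per-participant scaling)
  matches the single-intercept interpretation of β₀: participant baseline
  differences are the job of the participant random intercept, not of the
  scaling. A `scope="per_participant"` switch exists for exploration.
* Non-responses are recorded as `response="none"` and excluded from both
  models. No RT outlier trimming is applied by default; the filtering layer
  is the place to add one if a study design requires it.

Codings are fixed: gender feminine = 0 / masculine = 1, condition
unmarked = 0 / contracted = 1, so β_gender is the masculine-minus-feminine
contrast in the gender-unmarked condition and the interaction measures how
much the contracted double form changes that contrast.

## The two likelihoods

**Gaussian RT model.** `RT_z = α_{p,i} + β_gender·gender (+ condition
terms) + ε`, `ε ~ N(0, σ)`, with the crossed intercept
`α_{p,i} = β₀ + β_participant + β_item`, `β_participant ~ N(0,
σ_participant)`, `β_item ~ N(0, σ_item)`.

**Lapse-rate accuracy model.** `P(correct) = 0.5 + (0.5 − p_miss)·p` with
`logit(p)` following the same crossed linear structure, fitted to yes/no
correctness of all experimental trials. The chance level is anchored at 0.5
(two-choice task) and `p_miss`, shared across participants, sets the upper
asymptote at `1 − p_miss`. The two models are fitted separately; their
intercept sets are independent.

**Priors.** `β_X ~ N(0, 1)` for every fixed effect (data are standardized),
`σ_X ~ Gamma(2, 0.1)` (shape/rate) for every dispersion parameter, and
`p_miss ~ Beta(5, 10)` (prior mean 1/3). The experiment-2 variant adds
β_condition and β_gender×condition to both models; nothing else changes.

## Sampler

Fitting uses a Hamiltonian Monte Carlo engine written for these two
posteriors (with a generic fallback driver for small bespoke models):

* non-centred parameterization of both random-intercept vectors (deviations
  are `σ·z`, `z ~ N(0,1)`), which avoids funnel geometry at small σ;
* unconstrained scale: `log σ` and `logit p_miss`, with Jacobians included.
  Note the sampler follows the Beta(5,10) support (0, 1) for `p_miss`; the
  deterministic `accuracy_prob` helper enforces the stricter [0, 0.5) domain
  in which the psychometric function is guaranteed monotone increasing;
* dual-averaging step-size adaptation (target acceptance 0.9) with the
  step clamped to `exp([-18, 7])`, and a diagonal mass matrix estimated from
  the middle warmup window (Stan-style shrinkage toward a small constant);
* jittered leapfrog trajectories with total integration time 3.0 in
  mass-standardized units (chosen for ESS per second on a 47 × 22 fit),
  capped at 128 steps;
* an energy-error threshold of 1000 marks a trajectory as divergent
  (rejected, counted post-warmup);
* analytic gradients, checked in the test suite against finite differences
  and against an independent scipy density implementation.

Defaults mirror the reference analysis: 7 chains × 7,000 iterations, 3,000
burn-in, estimates on 4,000 per chain. Two light profiles serve the
simulation harnesses: `fast` (4 × 2,000) and `reduced` (2 × 1,200).
Initialization is uniform(−2, 2) on the unconstrained scale with
deterministically derived per-chain seeds; a fixed (seed, data, spec, MCMC)
combination reproduces draws bit for bit. Convergence is assessed with
split R-hat (≤ 1.01), bulk ESS (≥ 400) and the divergence count (0); a
failing fit warns and is flagged, never silently accepted.

## Posterior analysis

Summaries are equal-tailed quantile intervals (95% and 99%) with the
posterior mean; equal-tailed matches the symmetric presentation of such
results and the 99% contour is likewise a pair of quantiles. Quantiles use
the standard linear-interpolation rule; the suite pins this against a
sort-based oracle.

**Item-intercept correlation.** The per-item posterior-mean intercept
deviations of the RT and accuracy models ("vectors of random intercepts",
read as item-wise point estimates) are joined in a small bivariate Gaussian
model: means `N(0, 1)`, scales `Gamma(2, 0.1)`, and a uniform prior on the
correlation via `r = tanh(u)`. The posterior mean and 95% CI of `r` are
reported, alongside the plug-in Pearson estimate for transparency. Because
point estimates are shrunken and noisy, the estimated correlation is
attenuated toward zero relative to the generative item-level correlation —
a property of the estimator, not a bug.

**Prior-sensitivity sweep.** Refits the model with the prior scale of the
named fixed effects multiplied by each value of a grid (default 0.25–4) and
tabulates the movement of their posteriors; with informative data the means
barely move, in the prior-only limit the CI width is proportional to the
scale. Both limits are tested.

## Synthetic-data generator

The generator inverts the models exactly: it draws participant and item
intercepts from centred Gaussians, builds the linear predictors on the
counterbalanced design, adds Gaussian residuals on the z scale for RT and
draws responses from the lapse-rate psychometric function. The two-list
counterbalancing is explicit: within a list half the items take *il* and
half *elle*; across the two lists every item appears once with each pronoun
gender; participants alternate lists; experiment 2 splits participants
between conditions (between-subjects), with an optional `(n₁, n₂)` pair to
reproduce unequal groups such as 34/36.

Default `TrueParams` encode the study conditions the package is designed
around: β_gender(RT) = −0.22 z, β_gender(acc) = 1.49 logits, p_miss = 0.06,
condition/interaction effects of −0.17/+0.26 (RT) and +0.20/−0.39 (logits),
and an item-level RT–accuracy intercept correlation of −0.43. The RT
dispersions (σ_participant = 0.40, σ_item = 0.30, σ_resid = 0.85) are chosen
so the marginal z variance is ≈ 1, consistent with data that will be
re-standardized downstream; the accuracy dispersions (0.80 / 0.60 logits)
are typical participant/item heterogeneity for ~85–90% tasks. Generated z
values are mapped to ms via an affine back-transform (mean 1,500 ms,
SD 400 ms — the magnitude of the descriptive statistics in this paradigm),
floored at 50 ms (clamping counted in `attrs`), and rounded to the CSV
dialect's 3 decimals, so the full pipeline including re-standardization is
exercised. RTs are recorded for all trials, but the RT model only ever sees
positive responses.

What the generator does *not* emulate: RT distributions are Gaussian on the
z scale (no right skew, no ex-Gaussian tail), there are no sequential or
fatigue effects, no speed–accuracy trade-off within participant beyond the
item-level correlation, fillers are inert (deterministically correct), and
there are no timeouts. Passing recovery tests therefore demonstrate that
the estimation machinery is correct under the models' own assumptions, not
that the models are adequate for any particular real dataset.

## Stimulus norming

Ratings arrive per rater and word as a feminine percentage (a 60% feminine
rating is 40% masculine); scale-direction counterbalancing is assumed to be
resolved upstream. Word norms are the mean and sample SD of the masculine
percentage plus a missingness rate. Selection is a deterministic
three-step filter: keep the `k_closest = 25` words nearest 50% masculine
(ties: smaller SD, then lexicographic), drop words with SD above
`sd_max = 19.0`, drop words unknown to more than `missing_max = 10%` of
raters. No single numeric SD cutoff is canonical; 19.0 separates the
dispersion range of retained items (up to ≈ 17.9) from clearly unstable
ones (≈ 19.8 and above) and is exposed as a parameter. Rankings use exact
means (no rounding).

## Validation harnesses

* **Parameter recovery** at fixed generative values: bias, RMSE and 95%-CI
  coverage per parameter over replicated simulate → fit → summarize runs;
  replicates failing convergence are re-run once with a shifted seed, then
  excluded with a log entry.
* **Simulation-based calibration**: true parameters drawn from the model's
  own priors, data generated directly from the likelihood on the reduced
  10 × 6 design, ranks of the true values among 19 thinned posterior draws
  tested for uniformity (χ², α = 0.01). RT data are generated on the
  z scale here, because re-standardizing data whose σ's come from the wide
  Gamma(2, 0.1) prior would rescale the generative parameters and break the
  rank calibration.
* **Null calibration** of the correlation model: with independent intercept
  vectors the 95% CI covers zero at the nominal rate.

One known, deliberate limitation: at the reduced 10 × 6 design the lapse
rate is prior-dominated (60 binary trials cannot overcome Beta(5, 10)), so
the posterior mean for a generative `p_miss = 0.06` sits near 0.15 and the
95% CI frequently excludes 0.06. This is not a sampler defect — SBC rank
uniformity for `p_miss` holds exactly under the prior — but the familiar
fact that Bayesian intervals have no fixed-truth frequentist coverage
guarantee at a value in the prior's tail and a small n. At the full study
size (≈ 1,000 trials) the `p_miss` posterior concentrates near the
generative value (mean ≈ 6–8%, CI ≈ 4–11%).

## Problem sizes used by the harnesses

Recovery and calibration loops run at the reduced 10 × 6 design with the
light MCMC profiles (50 recovery replicates; 200 SBC replicates; 200
null-calibration replicates), which keeps each harness in the tens of
seconds to a few minutes on one CPU while leaving the binomial/χ² checks
adequately powered. Headline fits (the acceptance script and the worked
example) run at the full study sizes with the reference 7 × 7,000 settings.
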