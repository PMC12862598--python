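# Methods

## Setting and estimands

The package targets marginal exposure effects in a closed cohort observed
from a common baseline: the risk ratio `RR_t` at horizons t ∈ {1, 3, 5}
years, the hazard ratio `HR`, and the incidence rate ratio `IRR`, each
comparing exposed with unexposed under confounding by baseline covariates
(sex, age, race/ethnicity, state of residence, enrollment period).
Confounding is removed by stabilized inverse-probability-of-treatment
weighting; the outcome models contain only the exposure term, so all three
estimands are marginal (population-level) contrasts.

Because the hazard ratio is non-collapsible, the marginal `log HR` that an
IPW-weighted Cox model targets is *not* the conditional coefficient used to
generate data. `marginal_oracle` therefore computes the target values by
potential-outcome simulation: each of n simulated subjects contributes both
exposure arms under shared latent uniforms (same event-time uniform, same
censoring draw), the marginal `log HR` is the Cox coefficient fitted to the
stacked two-arm data, the marginal risks use the closed-form conditional
exponential risks averaged over covariates (net risks — the weighted
Kaplan–Meier complement's estimand under independent censoring), and the
marginal rate ratio applies the configured censoring to both arms. The
recovery tests compare estimator means against these oracle values, never
against the conditional generator coefficient.

## Synthetic cohort generator

Covariates are drawn independently per subject (sex Bernoulli, age uniform
18–64 by default, race/state/period categorical); exposure is Bernoulli on a
logistic index of the covariates; the latent event time is exponential with
rate `λ₀ · exp(βA + γ'L)`; censoring is exponential and truncated at the
administrative horizon (5 person-years). Exponential event times make the
conditional proportional-hazards assumption hold exactly, so the Cox estimand
is unambiguous. A follow-up of exactly zero is replaced by the smallest
positive double. Latent draws can be returned for debug-mode invariant
checks (`event = 1 ⇔ E ≤ min(C, horizon)`).

Two scenarios are provided. `medicaid_like` reproduces the structure of a
very large claims cohort: exposure prevalence 0.006, five-year event
incidence 0.001, censoring rate 0.5/year (chosen so mean follow-up is
~1.8 person-years over the 5-year horizon, the ratio seen in cohorts of this
type). `desk_scale` rescales to prevalence 0.05 and five-year incidence 0.02
with censoring 0.1/year, because sub-1% prevalence needs millions of
subjects for stable estimates; it keeps strong sex/age confounding (the
crude Cox estimate is biased upward by ≈ 0.4–0.5 on the log scale). In both
scenarios the exposure-model intercept and the baseline hazard are solved
numerically (Brent's method on a fixed 200,000-draw internal Monte-Carlo
sample) so the marginal prevalence and net incidence hit their targets; the
calibration is deterministic and independent of analysis seeds.

What the generator does **not** emulate: time-varying exposure or
confounding, informative censoring, competing events, measurement error,
missing data, or within-subject correlation. Passing tests therefore show
that the designs, weighting, estimators, and variance machinery behave
correctly under the stated data-generating assumptions — not that any of
them is robust to violations of those assumptions in real claims data.

## Designs and weighting conventions

- **Full**: everyone, π = 1.
- **Divide**: a uniformly random permutation split into K contiguous blocks
  (sizes differ by at most one); each block is analyzed as a full-style
  design; estimates recombine by fixed-effects inverse-variance
  meta-analysis.
- **Subcohort**: all exposed (π = 1) plus an exact-size simple random sample
  without replacement of `round(f·N₀)` unexposed (π = f). Exact sizes, not
  Bernoulli sampling, keep draws deterministic given the seed; it follows
  that `Σ 1/π` equals n exactly whenever `f·N₀` is integral and within
  `0.5/f` of n otherwise.
- **Case-cohort**: the subcohort plus every case not already sampled, at
  selection weight 1. Since every case reaches the analysis set with
  certainty (through the subcohort or the augmentation), the inclusion
  probability of a case is 1, and π = f applies only to sampled unexposed
  non-cases. This is the only assignment that keeps the weighted event mass
  unbiased with one record per subject: putting π = f on in-subcohort cases
  would count an unexposed case's event with expected weight `f·(1/f) +
  (1−f)·1 = 2 − f`.

The exposure model (logistic in sex, cubic B-spline age, race, state,
period) is weighted by 1/π, so it estimates the full-cohort propensity from
the sampled data; in a case-cohort every member appears once, so fitting on
the members is fitting on unique individuals. The stabilized numerator is
the 1/π-weighted marginal prevalence, consistent with the weighted
denominator model. Weights are not truncated by default.

Analysis rows are counting-process records `(start, stop]`, one per subject.
Ordinary members contribute `(0, time]` at weight `ipw/π`. Non-subcohort
cases contribute `(time − 0.001, time]` at weight `ipw·1`: the single
encoding serves all three estimands, since the Cox/KM risk sets read the
late entry directly and the Poisson estimator consumes `stop − start` =
0.001 person-years. Risk sets are open on the left (`start < u ≤ stop`), so
a late entrant is at risk at its own event time. A non-subcohort case with
follow-up ≤ 0.001 is clamped to `(0, time]` with a logged warning.

**Known approximation.** The case-cohort design under-represents the
pre-event person-time of the `(1−f)` cases outside the subcohort (they
contribute 0.001 py instead of their history) and carries subcohort cases at
weight 1 rather than 1/f. The resulting downward log-scale bias is of order
`incidence × (1−f) × (case person-time share)` — about −0.008 at the
desk-scale 2% incidence (measurable against the full-sample estimate with
paired designs), about −0.0006 at a realistic 0.1% incidence (negligible).
This is the standard rare-disease approximation of the design, not an
implementation artifact.

## Estimators and numerics

All iterative fits are authored in-package and validated against independent
oracles (hand product-limit computations, a brute-force partial-likelihood
maximization, saturated-logistic and two-group-Poisson closed forms,
statsmodels and lifelines cross-checks) rather than trusted:

- *Weighted logistic IRLS*: Newton with step halving; converged when the
  relative log-likelihood change is < 1e-8 (max 100 iterations). Rank
  deficiency is diagnosed by pivoted QR and reported with the aliased term
  names; perfect separation (fitted probabilities within 1e-10 of 0/1 with
  |β| > 30) raises an error suggesting covariate coarsening.
- *Weighted Cox (single binary covariate)*: Breslow tie handling, scalar
  Newton with step halving, convergence at relative log-likelihood change
  < 1e-9 (max 50 iterations). A monotone likelihood is detected *a priori*
  from the sign of the score at β → ±∞ (weighted exposed-event mass versus
  the event mass at times where only one group is at risk) and raises a
  "non-finite MLE" error; |β| > 50 is a backstop. Risk-set sums use sorted
  cumulative weights (O(n log n)), so group totals are computed once and
  only the scalar `e^β` varies across Newton steps.
- *Weighted Poisson IRLS*: offset `log(stop − start)`; same convergence rule
  as the logistic (1e-8, max 100); the two-parameter closed form (weighted
  crude rate ratio) is a test oracle, not a code path.
- *Robust sandwich* `A⁻¹BA⁻¹`: `A` is the weighted observed information; `B`
  sums squared cluster totals of weighted scores — Cox score residuals in
  martingale form for the Cox model, `w(y − μ)x` for the Poisson. Each
  subject is one cluster; bootstrap resamples get fresh ids so duplicates
  are independent clusters.
- *Kaplan–Meier complement*: product over distinct event times in ascending
  order; an event time with zero weight at risk raises an error naming the
  time; a zero risk in either group makes `log RR` an error rather than
  ±inf.

Ages outside the spline's boundary knots are clamped to the boundary with a
logged warning. Interior knots default to the 33.3rd/66.7th weighted
percentiles of age; the basis is a cubic B-spline with 2 interior knots
(6 columns, the first dropped against the intercept). A natural/restricted
spline with 2 knots would degenerate to a line, defeating the flexible age
term, so the unrestricted basis is used.

## Variance estimation

`BootstrapSpec` defaults to B = 500 resamples (a practical minimum for
SD-based SEs); tests and the acceptance script use B = 60–200 to keep run
times in minutes. Replicates resample n subjects with replacement and re-run
the entire pipeline — design draw with a replicate-specific seed, exposure
model refit, weight composition, estimation — because the weight-estimation
and sampling steps are part of the procedure whose variability the SE should
reflect. Stages: `from_full` (full/subcohort/case-cohort) resamples the full
cohort before the design draw; `before_split` (divide) draws the partition
once and bootstraps within each subsample, feeding per-subsample SEs to the
meta-analysis. The SE is the SD (denominator B−1) of replicate log
estimates; 2.5/97.5 percentile intervals are returned alongside Wald
intervals. Replicate failures (e.g., a resample with no exposed events) are
excluded up to a 5% failure budget, beyond which the bootstrap errors out.

Per-replicate seeds are `SeedSequence(entropy=seed, spawn_key=(b,))`, so
results are bitwise reproducible, independent of worker count (joblib) and
of input row order (the cohort is sorted by id before resampling).

For divide + RR, the inverse-variance recombination needs per-subsample SEs
and the risk ratio has no analytic one; each subsample gets an inner
bootstrap (default 50 replicates) before recombination. Divide + HR/IRR
recombine on robust sandwich SEs.

## Problem sizes in the tests and acceptance script

The statistical acceptance tests use 200 cohorts of n = 50,000 (parameter
recovery and design consistency, desk-scale scenario), 200 cohorts of
n = 20,000 against one B = 200 bootstrap (calibration), and 4 cohorts of
n = 12,000 with B = 60 (variance ordering); the oracle uses 2,000,000
potential-outcome pairs. `scripts/acceptance.py` analyzes one n = 50,000
cohort with B = 100 bootstrap replicates and a 1,000,000-pair oracle. These
sizes make the whole suite run in minutes on one CPU while leaving
Monte-Carlo error well below the effects being checked.

## Known limitations

- With few exposed events per analysis unit, `log` ratio estimates carry a
  finite-sample bias of order `−1/(2·d₁)` (d₁ = exposed events). This is
  visible in divide-and-recombine at desk scale: K = 10 splits of a 50,000
  cohort leave ~5–7 exposed events per subsample, biasing the recombined
  log HR downward by ~0.06 — an intrinsic property of splitting, echoed by
  the drift of many-split analyses at full scale, not a defect of the
  recombination. Use divide only when each subsample retains ample events.
- The case-cohort rare-disease approximation above.
- The robust Poisson SE under case-cohort sampling is reported but not
  trusted; the bootstrap SE is the default for the IRR, and both are exposed
  so their disagreement can be examined.
- Only baseline (time-fixed) exposure and covariates; no censoring weights,
  competing risks, doubly robust estimators, or weight-truncation-by-default.
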