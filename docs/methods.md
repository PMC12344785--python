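# Methods

## Design and estimand

The package emulates a two-arm pragmatic trial from observational register
tables. Time zero is the incident diagnosis; follow-up is partitioned into
consecutive 30-day intervals (half-open `[30t, 30(t+1))` in days since
index; one full interval contributes 1/12 person-year, a partial final
interval contributes pro rata). The default strategies are *initiate drug
treatment within a grace period of `g = 3` intervals and remain on it*
versus *never initiate during follow-up*; an active-comparator variant
(stimulant vs non-stimulant initiators, time zero at initiation) reuses the
same machinery without cloning.

Every eligible person is cloned into both arms at time zero, so the arms are
exchangeable by construction at baseline. A clone is artificially censored at
the first interval whose observed data contradict its assigned strategy:

* initiation arm — at interval `g` if treatment was never started before it;
  at definitive discontinuation whenever detected (stopping treatment
  deviates from "remain on therapy" even inside the grace window); at a
  post-grace class switch unless switching is allowed (a within-grace switch,
  while still treated, is not a deviation);
* non-initiation arm — at the interval of the first dispensation.

Exposure is reconstructed from dispensations by days-supply coverage with
carryover; an uncovered gap of at most `max_gap_intervals` (default 1) after
the last covered interval still counts as treated, so discontinuation is
*detected* one interval after supply actually ends. This one-month exposure
misclassification is intrinsic to dispensation data and pulls estimates
slightly toward the null; the synthetic generator reproduces it faithfully
(the reconstruction test pins the offset).

The per-protocol estimand targeted by the weighted contrast is the marginal
hazard ratio between the regimes "behave naturally during the grace period;
never-starters begin treatment at the grace boundary; sustain thereafter"
and "never initiate". The grace-period part is forced by the design: during
grace the initiation arm is the uncensored natural cohort with unit weights,
so its hazards there are the natural ones. The counterfactual oracle
(`simulate_counterfactual_truth`) simulates exactly this regime pair and
summarises it with the same pooled logistic functional the analysis uses, so
oracle and estimator target the same quantity. An aggregate
events-over-person-time ratio is *not* used as the truth because depletion
interacting with covariate heterogeneity makes it a slightly different
marginal summary.

## Censoring models and weights

One pooled logistic censoring model is fitted per arm on person-intervals at
risk (uncensored rows plus the first censored row), with saturated interval
dummies plus baseline covariates and the lag-one time-varying confounder.
Numerical and structural choices:

* **Saturated time, exact degenerate cells.** Intervals with no censoring
  events among at-risk rows get fitted censoring probability exactly 0, and
  all-censored intervals exactly 1 — the maximum-likelihood limit of the
  dummy model. A smooth-in-time fallback would impose positive censoring
  hazard where deviation is structurally impossible (e.g. the non-initiation
  arm after the grace period, when nobody initiates any more) and inflate
  weights spuriously. A polynomial `time_form` remains available as config.
* **Separate models per deviation mechanism.** Within the initiation arm,
  within-grace discontinuation, grace-end "never started", and post-grace
  deviation are fitted separately. A single composite fit lets the large
  grace-end censoring mass dilute the shared time-varying-covariate
  coefficients, leaving the discontinuation selection essentially
  uncorrected (verified by simulation: under discontinuation-only
  confounding, a composite model's weighted estimate equalled the unweighted
  one).
* **Grace history.** The grace-end model conditions on the confounder's full
  monthly history over the grace window, not only the last lag: not having
  started by the boundary depends on every monthly state that fed an
  initiation decision.
* **Weights.** `w_it = Π_{k≤t} 1/p̂_ik` over the clone's uncensored
  intervals; stabilized weights multiply by the analogous marginal
  (covariate-free) product. Unstabilized weights are the default. Weights
  are undefined on censored rows.
* **Truncation.** Per-arm percentile capping (numpy's linear-interpolation
  quantile), default 99.5. Truncation is a bias-variance tradeoff: it clips
  precisely the large late-follow-up weights that carry the
  high-confounder strata, and in the package's null scenario at n = 20 000
  it moves the mean weighted IRR from 1.001 (untruncated) to 0.985. The
  consistency checks in the validation suite therefore run untruncated,
  while the truncation arithmetic is validated separately; analyses follow
  the 99.5 default unless configured otherwise.

Event/censoring ties: an event in the first deviating interval is counted
(and censoring deferred by one interval) when its date is on or before the
deviation date, taken as the first day of the deviating interval.

## Outcome models and inference

The outcome fit is a weighted pooled logistic regression of the event
indicator on strategy arm and saturated interval dummies over uncensored
rows; `exp(β)` approximates the IRR while per-interval hazards are small
(the generator keeps monthly hazards below 0.05, where the odds/rate gap is
well under Monte-Carlo noise). Intervals with no events carry no information
about `β` under saturated time and are dropped to keep the MLE finite.
First-event panels stop at the event; recurrent panels cap events at one per
interval (repeat care contacts within a month are not separate events) and
continue person-time past events.

All pooled logistic fits use a package-authored Newton solver that exploits
the block structure of dummy-time designs (diagonal time block, Schur
complement on the covariate block), warm-started across bootstrap resamples;
it matches `statsmodels` GLM coefficients to ~1e-14 in the test suite but
makes a full pipeline refit cost tens of milliseconds, which is what renders
the person-level bootstrap (rerunning cloning, censoring, weight fitting and
outcome fitting in every resample) and the coverage study feasible on one
CPU.

Confidence intervals: nonparametric bootstrap over persons at original
cohort size, 500 resamples by default, percentile intervals computed on the
log-IRR scale and back-transformed (hence equivariant under `exp`); failed
resamples are excluded and counted, with more than 10% failures an error.
Subgroup contrasts use Wald z-tests on bootstrap standard errors and require
disjoint subgroups. A delta-method Poisson-type approximation
`sqrt(Σ_arm Σ(w·event)² / (Σ w·event)²)` to the SE of the log IRR is
attached to every estimate as a cheap Monte-Carlo error scale.

## The synthetic register generator

The generator emulates the structure of national health and prescription
registers: ~57% of the cohort initiates within the 3-month grace period;
baseline covariates (sex, age with median ≈ 17, education, a psychiatric
comorbidity flag, outcome history, psychotropic co-medication, healthcare
use) shift initiation (negatively) and the outcome hazards (positively); a
persistent binary time-varying confounder raises discontinuation (log-odds
1.2) and outcome (log-odds ≈ 0.8) hazards and, by default, responds to
treatment (log-odds −0.7), creating treatment-confounder feedback; monthly
discontinuation runs around 6–8%; death/emigration is rare (0.08%/month);
dispensations are emitted with supplies in {30, 60, 90} days aligned so that
coverage reconstruction inverts the simulated exposure exactly; the
time-varying confounder surfaces only as dated diagnosis records read back
with a one-month lag; six outcome processes (five outcome types plus a
type-1-diabetes-style negative control with no covariate or treatment
effects) generate dated events, recurrent by default. Monthly outcome
hazards put weighted rates in the tens-to-low-hundreds per 1000
person-years, the order observed in registry studies of behavioural
outcomes.

Randomness is laid out as one fixed-size uniform block per person inside a
single row-major draw, so growing `n_individuals` appends new people without
perturbing existing ones; the oracle uses separate streams.

What the generator does *not* emulate: calendar-time trends, realistic
diagnosis/drug coding, dose, supply ambiguity (overlapping or partial
fills), re-entry after emigration, family structure, and initiation after
the grace period. Passing tests therefore demonstrate correctness of the
design's mechanics and its consistency under the stated confounding
structure — not robustness to the messiness of real registers.

## Validation scenarios and problem sizes

The validation suite (`ccw.scenarios`, `tests/test_acceptance.py`,
`scripts/acceptance.py`) uses:

* **Null recovery** — n = 20 000, ten replicates, confounded initiation
  (baseline covariates and lagged confounder) and discontinuation
  (confounder), `true_log_irr = 0`, *no* treatment effect on confounder
  dynamics (with feedback on, a zero direct effect is not a marginal null:
  the truth is ≈ 0.92). Pass: mean log IRR within 2 Monte-Carlo SEs of 0.
* **Effect recovery** — same structure with conditional IRR 0.85, eight
  replicates; truth from the oracle at n = 250 000. Pass: weighted mean
  within ±0.05 of truth and under a third of the unweighted bias (measured
  weighted bias ≈ +0.01, unweighted ≈ −0.11). Where a Monte-Carlo SE is
  estimated from the replicates themselves, the two-SE rule uses the
  matching Student-t quantile.
* **Immortal time** — the naive ever/never comparison classifies exposure
  from dispensations observed during follow-up and counts all person-time
  from diagnosis; under the null it lands far below 1 (≈ 0.75) while the
  clone-censor-weight estimate stays at the null.
* **Balance** — at the end of grace, several covariates exceed |SMD| ≥ 0.10
  unweighted; all fall below 0.10 after weighting.
* **Coverage** — 100 replicates at n = 5 000 with 100 resamples each, on a
  reduced scenario (two active baseline covariates plus the confounder) so
  the lean censoring model is exactly specified and each refit stays cheap.
  The replicate sizes here are chosen to keep the whole validation suite in
  the tens of minutes on a single CPU while leaving Monte-Carlo error well
  inside the asserted bands.

## Known limitations

* Weight truncation at high percentiles biases toward the unweighted
  estimate (quantified above); stabilized weights mitigate but do not remove
  this.
* The grace-end censoring model is logit-additive in covariates while the
  true cumulative non-initiation probability is not exactly so; residual
  bias from this source was below Monte-Carlo resolution (≲ 0.01 IRR) in all
  measured scenarios.
* The pooled-logistic IRR approximation degrades if monthly hazards exceed
  a few percent.
* Recurrent-event inference relies entirely on the person-level bootstrap
  for within-person correlation.
* The active-comparator variant shares the censoring machinery but has no
  counterfactual oracle wired up and is exercised by smoke tests only.
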