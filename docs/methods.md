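# Methods

## The estimation problem

A waitlist registry records, per listing episode, calendar dates of
registration and exit (death, transplantation, delisting, or administrative
censoring), irregularly timed biomarker reports (creatinine mg/dL,
bilirubin mg/dL, INR, biweekly-dialysis flag), and non-transplantable (NT)
intervals. The goal is to re-estimate the coefficients of a MELD-type
90-day mortality score and to quantify how two methodological choices
change the result: sampling follow-up from calendar-time cross-sections
rather than from registration, and correcting for the dependent censoring
that transplantation and delisting induce.

### From-cross-section datasets

Cross-section dates form a weekly arithmetic grid. At each date, every
registration that is active (listed, not exited, not in an NT interval
`[start, end)`) and has a biomarker report dated on or before the date
contributes one row. Follow-up runs from the cross-section in day
granularity, administratively stopped at 90 days and at the registry
cutoff. A delisted patient who dies within 90 days of delisting is an
event at the exit date; other delistings and all transplants censor.
The Cox stratum is (country × cross-section date); rows repeat patients,
so every resampling procedure and the default standard errors cluster on
`patient_id`. The report lookup is inclusive (`report_date <= cs_date`),
matching how allocation uses the score reported on the date itself;
an exclusive variant is a switch.

### The partial-likelihood engine

All fits go through one engine (`dynremeld.cox`): Newton–Raphson on the
weighted Efron partial likelihood over counting-process records
`(start, stop]` in whole days, with per-interval case weights, a fixed
offset on the log-hazard scale, stratification, and a Breslow-type baseline
cumulative hazard per stratum. Risk sets are accumulated with
difference-array prefix sums over a (stratum × day) grid, so one
likelihood/gradient/Hessian evaluation is O(rows + strata × days);
convergence is declared when the Newton step falls below 1e-9 with
step-halving guarding ascent. A singular information matrix raises rather
than regularizes. Model-based covariance is kept alongside the
patient-clustered sandwich covariance; the sandwich (computed from
Breslow-form score residuals) is the default for mortality fits because
cross-section rows of one patient are strongly correlated and model-based
standard errors would overstate precision several-fold. Point estimates and
standard errors were validated against lifelines (weighted/stratified,
counting-process, and cluster-robust cases) and against direct numerical
maximization of an independently coded likelihood.

### Adjustment set and caps

The mortality model adjusts for log capped creatinine with creatinine set
to 1.0 mg/dL under dialysis (so the term carries no information for
dialysis patients), log capped bilirubin, log capped INR, and a dialysis
indicator. Biomarker bounds can be fixed (the published 0.8–2.5 / 0.6–55 /
1.0–3.0 set) or optimized by a coordinate-wise likelihood search: each
biomarker's (lower, upper) pair is optimized over a candidate grid holding
the others fixed, sweeping creatinine → bilirubin → INR until stable (at
most 3 sweeps), ties broken toward wider bounds.

### Offset comparisons

To test whether an existing score (ReMELD) already explains 90-day
mortality, its points enter as a fixed offset and the likelihood-ratio test
(3 df) evaluates the added biomarker terms. Score points are not on the
log-hazard scale; the offset divides them by a scale factor. By default
that factor is estimated by quantile-matching the reference score against
the linear predictor of the offset-free fit on the same rows; it can be
supplied directly (the calibration study passes 1.0 with a generating-scale
score). The estimated scale is reported with the fit because an offset
mis-scaled by a constant changes the test.

### IPCW

Transplantation and delisting depend on biomarkers reported *after* the
cross-section, which the mortality model deliberately excludes — hence
dependent censoring. Each cause gets a cause-specific proportional-hazards
model on counting-process data whose covariates update at every
post-cross-section report (default covariates: the UNOS-capped log
biomarkers with the dialysis substitution, plus the dialysis flag; a
single implied-score covariate is also available). The joint weight at
follow-up time t is `1/(S_T(t|history) · S_D(t|history))`, assuming the two
causes conditionally independent given the history. Defaults: stabilization
by the marginal (covariate-free, stratum-specific) survival product, and
truncation at the 99th percentile of the weight distribution; both are
switches. Censoring models are stratified by country and pooled over
cross-sections so per-stratum risk sets remain estimable.

Weights are attached per interval and evaluated at the interval end; the
interval grid is the union of report times and a regular `split_days` grid
(default 14 days). When censoring hazards are large this end-point
evaluation overweights at-risk time within an interval — use daily
splitting (`split_days=1`) in high-intensity analyses. Because splitting
does not change the censoring-model likelihood, censoring models are
fitted on the unsplit expansion. In the weighted analysis frame the
biomarker columns are frozen at their cross-section values; only the
`cz_*` censoring covariates vary over intervals.

Two practical caveats found during development and worth knowing:

* truncation and stabilization control variance but clip exactly the
  large weights on high-severity deaths that carry the bias correction, so
  the untruncated estimator should be run alongside the default when the
  quantity of interest is an absolute risk;
* the delisting→death reclassification makes the naive estimator already
  count part of the mortality that delisting would otherwise censor; where
  delisting intensity grows with severity this *reverses* part of the
  expected naive-vs-IPCW contrast for absolute risks.

### Score derivation

The fitted linear predictor is affinely mapped to the UNOS-MELD point scale
by least squares on percentile pairs (grid: percentiles 1–99 of the
development cross-section rows). Coefficients are `scale × β` rounded to two
decimals, the intercept is the matched shift, and dialysis is handled by
substituting creatinine at its upper cap — justified when
`exp(β_dial/β_crea)`, the creatinine level with the same priority as
dialysis, is close to that cap.

### Evaluation

Discrimination uses a time-truncated concordance at 90 days: a pair is
comparable when one member fails strictly before the other's follow-up and
before the horizon; pairs carry weight `1/G(t-)²` with `G` a Kaplan–Meier
of the pooled censoring process by default (a model-based `S_T·S_D` product
or any user-supplied `G` gives the dependent-censoring variant). Score
comparisons bootstrap patients (all rows of a patient move together); the
p-value is a normal approximation on the replicate differences. Absolute
90-day risks per integer score come from a Cox model with the point score
as single covariate, fitted on rows deduplicated to each reported biomarker
set's first active cross-section; `risk(s) = 1 − exp(−H0(90)·e^{βs})` with
Breslow baseline and cluster-bootstrap intervals. Prediction is only
meaningful on the score range with data support; when sparse extreme
scores exist, restrict the fit to the tabulated range — extreme rows
otherwise dominate the weighted fit's slope. The proportional-hazards-free
check estimates per-score risks by Kaplan–Meier with each patient entering
a score stratum at the first report reaching that score; first-reach strata
at high scores select patients on upward trajectories, so pointwise
agreement with the prevalent-row Cox estimate deteriorates there and
agreement is summarized by the median across strata.

## The synthetic registry

The generator emulates the *dependence structure* the analysis relies on,
not any real registry's marginals:

* latent log-biomarkers follow a daily random walk; defaults: initial means
  (0.05, 0.85, 0.25) and SDs (0.30, 0.80, 0.22) on (log crea, log bili,
  log INR), common upward drift (0.0008, 0.0022, 0.0008)/day, volatility
  (0.012, 0.022, 0.009)/day. Drift heterogeneity (a progressor/stable
  mixture) is available via `progressor_fraction < 1` but off by default: a
  latent progressor class acts as a shared frailty and makes *any*
  fixed-covariate hazard model inconsistent, which would confound the
  censoring-bias comparisons the default scenarios exist for;
* reports are emitted at listing (mandatory), whenever the report age
  exceeds the recertification limit for the current reported UNOS-MELD band
  (≤10: 365 d, 11–18: 90 d, 19–25: 30 d, >25: 7 d — the published extremes
  with interior bands filled in), and voluntarily at 1%/day; reported
  values are rounded to registry precision and the rounded values drive
  all hazards, so the emitted tables fully determine the event processes;
* the daily death hazard is `9e-5 · exp(2.15·log crea* + 0.97·log bili +
  2.22·log INR + 1.86·dialysis)` on the *reported* values, with the
  creatinine term zeroed under dialysis — the same parameterisation the
  mortality model fits, so parameter recovery is a clean consistency check;
* transplant and delisting hazards are either constant (scenario
  `A_independent`: 1.5e-3 and 3e-4 per day) or log-linear in the current
  reported UNOS-MELD score (scenario `B_informative`: +0.12 and +0.08 per
  point), which keeps the default censoring model exactly correctly
  specified; an optional saturation cap on the score entering these hazards
  models the plateau of allocation intensity at the top of the list and
  preserves positivity in strong-allocation variants;
* competing events within a day are resolved by exponential waiting times
  under that day's hazards (ties: death > transplant > delisting); delisted
  patients continue a frozen death process for 90 days; 8% of patients get
  one NT interval; patients without an exit are censored at the window end.

Defaults were calibrated once so the 90-day event pattern from
cross-sections resembles a European liver waitlist (≈9–10% death, ≈15–18%
transplantation, transplant fraction rising steeply across score bands,
≈10% dialysis at listing). Window: two years, 3,000 patients, three
countries (one single-center) — sizes chosen to keep the replicate studies
tractable on one CPU.

What the generator does **not** emulate: real marginal distributions and
their correlations, exception points, center-level behaviour beyond random
assignment, re-transplantations, measurement error distinct from process
noise, and fast decompensation dynamics at the top of the score range.
Passing recovery tests here demonstrates estimator correctness under the
assumed dependence structure, not calibration to any real population.

## Known limitations

* Model-based absolute risks under IPCW are sensitive to weight truncation
  and to sparse extreme scores (see the caveats above); the package reports
  both weighted and unweighted tables so the contrast is visible.
* The c-index censoring correction defaults to a pooled Kaplan–Meier `G`;
  the model-based product is available but shares the censoring models'
  assumptions.
* Robust variance is a first-order sandwich; it does not propagate the
  uncertainty of the estimated weights (the cluster bootstrap does).
* The offset scale estimation introduces a dependence between the offset
  test and the offset-free fit on the same rows; supply a fixed scale when
  an exact pre-registered test is needed.
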