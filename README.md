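# dynremeld

Revision of MELD-family liver-allocation scores from **calendar-time
cross-sections** of a transplant waitlist registry, with
**inverse-probability-of-censoring weighting (IPCW)** for the informative
censoring caused by transplantation and delisting.

Liver transplant candidates are prioritized by the Model for End-stage Liver
Disease (MELD), a 90-day waitlist mortality score computed from serum
creatinine, bilirubin and the INR:

```
score = intercept + c_crea·log(crea) + c_bili·log(bili) + c_INR·log(INR)
```

with biomarkers clamped to score-specific bounds and creatinine substituted
for patients on biweekly dialysis. Re-estimating these coefficients the
conventional way — Cox models for 90-day mortality *from registration* —
discards every biomarker reported after listing and every death beyond the
first 90 days, and ignores that transplantation and delisting remove
patients informatively. This package implements the alternative:

* **from-cross-section datasets** — all actively listed, transplantable
  patients are sampled at weekly calendar dates and followed 90 days,
  adjusting for the last biomarker report on or before the sampling date;
  models are stratified by (country × cross-section); a delisted patient who
  dies within 90 days of delisting counts as a waitlist death at exit;
* **IPCW** — cause-specific extended Cox models for transplantation (IPCW-T)
  and delisting (IPCW-D) on counting-process data with time-varying reported
  biomarkers; the joint weight `1/(S_T(t|history)·S_D(t|history))` (optionally
  stabilized and truncated) reweights the mortality partial likelihood;
* **score derivation** — likelihood-optimized biomarker caps, quantile
  matching of the fitted linear predictor to the UNOS-MELD scale, and
  assembly of an allocation-style score definition;
* **validation** — time-truncated, censoring-corrected concordance with
  patient-cluster bootstrap comparisons, absolute 90-day mortality-risk
  tables with and without IPCW, and a Kaplan–Meier first-score-reach check;
* **a synthetic registry generator** with severity-driven recertification,
  biomarker random walks, and score-dependent transplant/delisting hazards —
  with known ground truth, so every estimator is testable.

It is written for biostatisticians and registry analysts working on
urgency-based allocation, and for anyone needing a weighted, stratified,
counting-process Cox engine with offsets and day-granular ties.

The built-in score definitions are UNOS-MELD (6.43 + 9.57·log crea +
3.78·log bili + 11.20·log INR), ReMELD, and DynReMELD
(8.50 + 9.12·log crea + 4.14·log bili + 9.42·log INR, creatinine bounded to
0.8–2.5 mg/dL, bilirubin 0.6–55, INR 1.0–3.0, dialysis → creatinine 2.5).

## Worked example

Simulate a 2,000-patient registry under informative censoring, run the full
revision pipeline (validate → center-based 70/30 split → datasets → IPCW →
fits → score derivation → validation):

```python
from dynremeld import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(n_patients=2000, n_boot=20, seed=7))
print(report["fits"]["from_cross_section"]["refit_ipcw"]["coefficients"])
print(report["derived_score"])
print(report["c_index"]["cross_section"])
```

prints (abridged):

```
{'log_creatinine': 2.105, 'log_bilirubin': 0.993, 'log_inr': 2.558, 'dialysis_f': 2.116}
{'scale': 4.0713, 'intercept': 7.44, 'coef_crea': 8.57, 'coef_bili': 4.04,
 'coef_inr': 10.42, 'dialysis_creatinine': 2.5,
 'dialysis_equivalent_creatinine': 2.7319}
{'UNOS-MELD': 0.7861, 'ReMELD': 0.7915, 'RevisedMELD': 0.7941,
 'delta_vs_UNOS-MELD': {'delta': 0.008, 'se': 0.0037, 'p': 0.0305}}
```

Read this as: the IPCW-weighted cross-section Cox fit recovers the
generator's true log-hazard ratios (2.15 / 0.97 / 2.22 / 1.86); quantile
matching rescales that linear predictor onto the UNOS-MELD point scale
(here scale ≈ 4.07, so e.g. 2.105 × 4.07 ≈ 8.57 points per log-unit
creatinine); `dialysis_equivalent_creatinine` is the creatinine level with
the same priority as biweekly dialysis, exp(β_dial/β_crea) ≈ 2.7 mg/dL,
close to the 2.5 upper cap that justifies the substitution rule; and on the
held-out validation centers the revised score discriminates 90-day waitlist
death from last-reported biomarkers better than UNOS-MELD (Δc = 0.008,
p = 0.03 by patient-cluster bootstrap).

The same stages are scriptable from a shell:

```bash
dynremeld score --score unos --creatinine 1.0 --bilirubin 1.0 --inr 1.0
# UNOS-MELD: 6.43 (rounded: 6)
dynremeld simulate --scenario B_informative --n-patients 2000 --seed 7 --outdir runs/demo
dynremeld run-all --scenario B_informative --n-patients 2000 --seed 7 --outdir runs/demo
```

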