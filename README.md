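# tigepk

Tigecycline is a broad-spectrum glycylcycline antibiotic used in
critically ill patients with complicated infections; it is mainly
biliary-excreted, and a few percent of treated patients develop elevated
aminotransferases. `tigepk` is a Python package for studying that
safety signal computationally. It chains together, as tested, reusable
modules:

* **`pk_core`** — a covariate-parameterized one-compartment IV-infusion
  population-PK model,
  `CL = (11.30 − 0.14·APACHEII)·e^η,  η ~ N(0, 0.065)` and
  `V = 105.00·(1 − 0.0059·AGE)·e^η,  η ~ N(0, 0.160)`,
  with closed-form multi-dose superposition, steady-state troughs, and
  the standard 10-point post-first-dose sampling grid
  {4, 8, 12, 24, 36, 48, 60, 72, 74, 78} h;
* **`bayes_feedback`** — MAP ("Bayesian feedback") individualization of
  (η_CL, η_V) from sparse measured concentrations under a
  proportional-error likelihood and the population priors;
* **`hepatotox_rules`** — deterministic three-level liver-status
  classification (none / liver-function injury / hepatotoxicity) from ALT
  and bilirubin series: injury = ALT twice in a row in (40, 120] U/L,
  hepatotoxicity = ALT twice in a row > 120 U/L, bilirubin > 1.5×ULN
  twice, or ALT > 1.5× an abnormal baseline twice;
* **`stats_pipeline`** — Kolmogorov–Smirnov-gated univariate statistics
  (t vs Mann–Whitney U, Pearson vs Spearman, mean±SD vs median(Q1,Q3))
  and the per-site 6:2:2 train/validation/test split;
* **`kan_predictor`** — a from-scratch Kolmogorov–Arnold network (learnable
  cubic B-spline edge functions, numpy only, fully seeded) for
  hospitalization-days regression and abnormal-liver-function
  classification, with AUC/sensitivity/specificity and MAE/RMSE reports;
* **`synthetic_cohort`** — a seeded generator of a virtual two-site
  263-patient cohort (sites 200:63, liver groups 202:50:11,
  hospitalization-day medians 20/23/30 days, age ~ 62 ± 18 on [14, 98])
  so every stage runs and is testable without any data download;
* **`pipeline` / `tigepk` CLI** — end-to-end orchestration with report
  tables, model metrics and a reproducibility manifest.

It is aimed at pharmacometricians and clinical-data scientists who want a
transparent, fully seeded sandbox for TDM-style individualization,
drug-induced liver injury screening rules, and spline-network outcome
prediction on tabular clinical data.

## Worked example

```python
from tigepk.pk_core import PatientCovariates, default_regimen, simulate_standard_grid
from tigepk.bayes_feedback import ConcentrationObservation, fit_map
from tigepk.hepatotox_rules import LabSeries, classify_liver_status

# typical 62-year-old, APACHE II 15, 100 mg loading then 50 mg q12h
cov = PatientCovariates(age=62, apache2=15, first_dose_mg=100)
profile = simulate_standard_grid(cov)
for t, c in zip(profile.times_h, profile.conc_ng_ml):
    print(f"{t:5.1f} h  {c:8.1f} ng/mL")

# individualize from two measured levels (2 h peak, 24 h trough)
obs = [ConcentrationObservation(2.0, 1500.0), ConcentrationObservation(24.0, 260.0)]
res = fit_map(obs, cov, default_regimen(100.0), seed=1)
print(f"eta_cl={res.eta_cl:+.3f}  eta_v={res.eta_v:+.3f}  "
      f"CL={res.params.cl:.2f} L/h  V={res.params.v:.1f} L")

# classify a liver series
status = classify_liver_status(LabSeries(alt_days=(1, 3, 5), alt_values=(35.0, 62.0, 55.0)))
print(status.label.name, "-", status.triggering_rule)
```

prints

```
  4.0 h     926.7 ng/mL
  8.0 h     533.2 ng/mL
 12.0 h     306.8 ng/mL
 24.0 h     211.9 ng/mL
 36.0 h     193.8 ng/mL
 48.0 h     190.3 ng/mL
 60.0 h     189.7 ng/mL
 72.0 h     189.6 ng/mL
 74.0 h     754.6 ng/mL
 78.0 h     434.2 ng/mL
eta_cl=-0.123  eta_v=-0.105  CL=8.14 L/h  V=59.9 L
INJURY - ALT in (40, 120] U/L twice in a row
```

The concentration grid shows the characteristic regimen shape: declining
12-hourly troughs settling onto the steady-state plateau (~190 ng/mL for
this patient), a rebound 2 h into the 72-h maintenance dose, and partial
washout at 78 h. The MAP fit reads the two measured levels as a patient
with ~12% lower clearance and ~10% smaller volume than the typical values
for that age and severity. The ALT series 35 → 62 → 55 U/L contains two
consecutive values in the injury band, so the patient is labeled with
liver-function injury.

The whole pipeline runs from the command line:

```bash
tigepk run-all --out results/run --n 263 --seed 42
```

which generates the cohort, classifies every patient, writes the six
report tables (baseline/split counts, liver-group vs laboratory p-values,
hospitalization-day group summaries, days-vs-indicator correlations,
concentration summaries per split, concentration-days correlations),
MAP-individualizes a patient subset, trains both KAN models, and records
checksums of every artifact in `manifest.json`.

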