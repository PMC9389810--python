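# cusum-gfr

Continuous monitoring of kidney function from routine laboratory data.
`cusum-gfr` watches each patient's serial estimated glomerular filtration
rate (eGFR) with an age-adjusted, one-sided cumulative-sum (CUSUM) control
chart and raises a signal when the accumulated decline suggests likely
progression to end-stage kidney disease (ESKD) — often years before the
diagnosis code appears.  It is aimed at clinical informaticists and
biostatisticians working with longitudinal EHR laboratory extracts, and at
methodologists who want a fully testable reference implementation with a
built-in synthetic cohort generator.

## The statistic

Serum creatinine is converted to eGFR with the 2021 CKD-EPI race-free
creatinine equation

    eGFR = 142 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^(−1.200) · 0.9938^age · (1.012 if female)

with κ = 0.7/0.9 and α = −0.241/−0.302 for females/males.  For each patient
the chart accumulates standardized downward deviations from a healthy,
age-adjusted reference mean:

    CUSUM₀ = 0
    CUSUMᵢ = min[0, (eGFRᵢ − μ̂ᵢ)/σ̂ + w + CUSUMᵢ₋₁]
    μ̂ᵢ    = μ̂₀ − 0.81·Δtᵢ

where μ̂₀ is the mean eGFR of a screened Normal group at the patient's age at
their first measurement, σ̂ the pooled within-age SD of that group,
0.81 mL/min/1.73 m²/yr the natural decline of healthy kidneys, Δtᵢ the years
since the first measurement, and w ≥ 0 an allowance that tunes how much
benign variation is forgiven per observation.  The min operator caps the
statistic at zero, so only sustained declines accumulate; the patient
signals at the first observation with CUSUMᵢ ≤ T for a non-positive
threshold T.  (w, T) are chosen by stratified 10-fold cross-validation over
a grid, maximizing mean accuracy with Youden's J as tie-break, and the
threshold sweep yields a ROC curve.

The package also implements the cohort-construction rules (acute-kidney-
injury exclusion, ICD-coded group assignment with wildcard matching,
minimum-measurement and eGFR-range filters), earliness analysis (days from
signal to diagnosis), subgroup performance, and a seeded generator of
synthetic longitudinal cohorts so that every stage runs without access to
protected patient data.

## Worked example

```python
from cusum_gfr import (SimConfig, simulate_cohort, build_cohort,
                       estimate_reference, kfold_tune, classify_cohort,
                       earliness_summary, metrics, CusumParams)

sim = simulate_cohort(SimConfig(n_normal=300, n_progressor=80, seed=1))
cohort = build_cohort(sim.raw_patients)
ref = estimate_reference(list(cohort.normal))
print(f"reference mean {ref.overall_mean:.2f}, sigma {ref.sigma:.2f}")

tuning = kfold_tune(cohort, k=5, seed=1)
print("best (w, T):", tuning.best)

records, counts = classify_cohort(cohort, ref, CusumParams(*tuning.best))
m = metrics(counts)
print(f"sensitivity {m.sensitivity:.3f}  specificity {m.specificity:.3f}")
print(f"mean earliness {earliness_summary(records).mean_days:.0f} days")
```

Output:

```
reference mean 83.80, sigma 7.69
best (w, T): (0.75, -6.0)
sensitivity 1.000  specificity 1.000
mean earliness 1513 days
```

The reference mean sits a little below the 85.07 entry anchor because the
cohort ages over follow-up; the synthetic progressors decline steeply enough
that the tuned chart separates them perfectly, signaling on average about
four years before the diagnosis date.

The same pipeline is scriptable from the shell:

```bash
cusum-gfr simulate --n-normal 300 --n-progressor 80 --seed 1 --out-dir sim
cusum-gfr tune sim/labs.csv sim/demographics.csv sim/diagnoses.csv --k 5
cusum-gfr evaluate sim/labs.csv sim/demographics.csv sim/diagnoses.csv
```

An sklearn-style estimator is also provided: `CusumGfrDetector(w, T)` with
`fit(X, y)` / `predict(X)` / `decision_function(X)` over arrays of
`MeasurementSeries`, usable with `cross_val_score` and `GridSearchCV`.

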