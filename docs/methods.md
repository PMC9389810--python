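# Methods

## Model and assumptions

The monitor is a one-sided, zero-capped CUSUM on standardized eGFR
deviations.  Its premises:

* Healthy (Normal-group) eGFR at a given age is approximately normally
  distributed around an age-specific mean μ̂₀(age) with a common residual SD
  σ̂, and declines linearly with age at d = 0.81 mL/min/1.73 m²/yr.  The
  age adjustment μ̂ᵢ = μ̂₀ − d·Δt removes this benign drift so the chart
  accumulates only pathologic decline.
* Deviations from μ̂ᵢ are treated as exchangeable across visits; no
  autocorrelation model is fitted (the generator can add AR(1) noise to
  probe robustness, see below).
* The chart is one-sided by construction: the min operator keeps the state
  ≤ 0, so rising eGFR can only restore the state to zero, never build
  positive credit.  Two-sided variants and average-run-length theory are
  out of scope.

eGFR is computed with the 2021 race-free CKD-EPI creatinine equation
(constants 142, 0.9938, 1.012, κ = 0.7/0.9, α = −0.241/−0.302, exponent
−1.200).  Age is fractional years at the measurement date on an
actual/365.25 basis, avoiding step artifacts in long series.  Creatinine
above 20 mg/dL is passed through with a warning rather than censored.  The
inverse (used only by the simulator) solves each power-law branch in closed
form; because eGFR grows without bound as creatinine approaches zero, the
attainable range is delimited by a physiologic creatinine floor of
0.05 mg/dL and targets above the corresponding eGFR raise a domain error.

## Reference estimation

μ̂₀ is tabulated per integer age over all Normal-group measurements; ages
not represented in the table fall back to the overall mean.  σ̂ is the
pooled **within-age** SD — the residual spread about the per-age means —
because that is the scale on which (eGFRᵢ − μ̂ᵢ)/σ̂ standardizes; the raw SD
over all measurements would also include between-age variance and inflate
σ̂.  The standard error of the overall mean treats the patient, not the
measurement, as the sampling unit (SD of per-patient means over √n
patients), since within-patient measurements are strongly dependent.
A one-sample Kolmogorov–Smirnov statistic against a normal law with the
estimated mean and SD is reported as a descriptive normality check (α =
0.05); with estimated parameters this test errs conservative, which is
acceptable for its screening role here.

## Selection rules and their boundaries

* Acute kidney injury: a patient is excluded when **all** their eGFR values
  are < 90 **and** the whole record spans ≤ 92 days (≈ 3 calendar months).
  The window is configurable; the reading excludes short acute episodes
  without discarding chronic low-eGFR patients.
* Group label: ESKD iff any diagnosis code matches the ESKD list (defaults
  585.6 / N18.6; matching is case-insensitive, exact or prefix with a
  trailing `*`); the diagnosis date is the earliest matching dated code, and
  an undated match is a data error.
* Normal group: no code in the (configurable) CKD exclusion list, no eGFR
  < 60 anywhere (strict), and ≥ 9 observations.
* ESKD group: first eGFR ≥ 60 (60.0 exactly is retained) and ≥ 2
  observations strictly before the diagnosis date.  Post-diagnosis
  observations are never scored: signaling after diagnosis is clinically
  moot, so any counted signal is a pre-diagnosis signal and a failure to
  signal before diagnosis is a false negative.
* Every exclusion is logged with a reason code, and input count =
  retained + logged exclusions at every stage.

## Tuning and evaluation

Grid defaults w ∈ {0.25, 0.5, 0.75, 1.0, 1.25}, T ∈ {−2, −3, −4, −5, −6}.
Folds are stratified by group label with a fixed seed so each fold contains
both classes; per-fold test metrics are averaged per grid point.  The best
point maximizes mean accuracy, with Youden's J and then larger |T| (the more
conservative threshold) as tie-breaks.  By default the healthy reference is
re-estimated inside each training fold, so the test normals never
contribute to the μ̂/σ̂ they are scored against; `refit_reference=False`
reproduces the simpler global-reference mode in which reference patients
are also scored as negatives.  Both modes are exposed because either is a
defensible reading of common practice; the default avoids leakage.

The ROC sweeps T at fixed w; since the signal rule is a threshold on the
per-patient minimum CUSUM value, sensitivity is non-decreasing and
specificity non-increasing as T rises toward zero.  AUC is the trapezoid
area with (0,0) and (1,1) anchors; a single-threshold grid reports a point
and no AUC.  Earliness (diagnosis date − signal date, calendar days) is
summarized over true positives only, with SE = SD/√n.
Subgroup tables stratify by sex, race, age band (65 split) or a comorbidity
flag, and compare earliness between levels with Welch's t.

## The synthetic cohort generator

The generator emulates the structure the method assumes, with defaults
anchored to the reference-cohort summary statistics:

* Healthy patients: entry age from a truncated normal (mean 64.5, SD 10,
  range 40–80); latent eGFR = entry mean − 0.81·t with entry mean anchored
  at 85.07 at age 64.5; independent Gaussian visit noise, SD 7.8; values
  below 60 are redrawn so the Normal-group definition holds; ≥ 9 visits
  guaranteed over a 5-year follow-up.
* Progressors: entry age mean 57.9; first eGFR ≥ 60 with entry level
  uniform on 70–100; trajectory shapes mixed 35% rapid drop (healthy drift
  until a change point at 0.5–3 yr, then a 10–25 /yr slope), 40% steady
  linear decline at 6–12 /yr, 25% convex exponential decay (rate
  0.25–0.5 /yr).  The diagnosis date is the latent trajectory's first
  crossing of eGFR 15 (closed form per shape); trajectories that cannot
  reach it within 12 years are resampled, with a config error after bounded
  retries.  All progressor excess slopes exceed the healthy decline by at
  least ~5 mL/min/1.73 m²/yr, giving a strongly separable cohort.
* Visit gaps: gamma-distributed (shape 1.5, mean 120 days, minimum 7),
  reflecting the wide practical variation of laboratory follow-up
  intervals; dates are rounded to whole days.
* Demographics and comorbidity flags are drawn per group from categorical
  distributions matching the reference cohort's proportions (e.g.
  hypertension 54% / 89%).
* Observations are emitted as serum creatinine by inverting the eGFR
  equation at the visit age, so consumers exercise the full conversion
  path.
* Optional decoys violate exactly one selection rule each (acute episode,
  an eGFR below 60, a CKD code, too few measurements, low initial eGFR, no
  pre-diagnosis observations), with the expected exclusion reason recorded
  as ground truth.

What the generator does **not** emulate: assay-type mixtures, unit errors,
duplicate records, informative visit timing, measurement autocorrelation
(unless `ar1_rho` is set), or realistic overlap between slow progressors
and fast-aging normals.  Passing tests on this cohort therefore demonstrate
correctness of the machinery and recoverability under the stated model, not
the clinical operating characteristics to expect on real EHR data, where
class separation is far weaker.

## Numerical choices and degenerate inputs

* Signal boundary inclusive: the patient signals at the first value ≤ T.
* The CUSUM state is never reset after a signal; only the first crossing is
  reported.
* μ̂₀ lookup uses integer-age bins (no interpolation); uncovered ages fall
  back to the pooled mean.
* One-observation series are valid and produce a one-value trace; an empty
  series is an error.
* σ̂ = 0 (e.g. a constant-eGFR reference) raises rather than silently
  dividing; empty metric denominators raise rather than returning 0.
* Ties in tuning are broken deterministically (accuracy, then Youden's J,
  then |T|), and all stochastic steps flow from a single integer seed.

## Problem sizes

The bundled verification runs use a 2,000-normal / 500-progressor cohort
for tuning and recovery checks, 100-patient cohorts across 50 seeds for the
normality-rejection rate, and 500–1,000 randomly drawn series for the
recursion-equivalence and monotonicity properties; these sizes give stable
estimates (binomial SE below ~1.5 percentage points on the rates) while
keeping the whole suite fast.

## Known limitations

* The acute-kidney-injury phrase "all eGFR < 90 within 3 months" admits
  several readings; the span-based operationalization here is one of them
  and is configurable.
* The default CKD exclusion list is a minimal stand-in; production use
  should supply the site's full coded list.
* Integer-age binning of μ̂₀ introduces sub-year step effects; the 0.81
  within-series adjustment operates continuously, so the effect is limited
  to the entry lookup.
* Performance numbers on the synthetic cohort (near-perfect separation) are
  a property of the generator's strong effect sizes, not a claim about real
  populations.
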