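"""Cohort construction: selection rules, group labels, reference estimation.

The selection flow mirrors routine EHR cohort building for kidney-function
monitoring:

1. compute eGFR for every creatinine observation;
2. drop acute-kidney-injury presentations (every eGFR < 90 and the whole
   record spanning at most ~3 months);
3. split the remainder by diagnosis code into an ESKD group (ICD-9 585.6 /
   ICD-10 N18.6, dated) and the rest;
4. the ESKD group keeps patients whose first eGFR is >= 60 and who have at
   least two observations before diagnosis;
5. the Normal group keeps non-ESKD patients with no chronic-kidney-disease
   code, no eGFR below 60 anywhere, and at least nine observations.

The Normal group then yields the reference: per-integer-age mean eGFR, the
pooled within-age SD, and the overall mean with a patient-level standard
error.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._exceptions import DataError, InsufficientDataError, InvalidInputError
from .cusum import DEFAULT_DECLINE_RATE, NormalReference
from .series import LabeledCohort, MeasurementSeries, RawPatient

DEFAULT_ESKD_CODES = ("585.6", "N18.6")
#: minimal stand-in for the chronic-kidney-disease exclusion list; the full
#: list is site-specific and supplied through configuration
DEFAULT_CKD_EXCLUSION_CODES = ("585*", "586", "N18*", "N19")

AKI_WINDOW_DAYS = 92  # "within 3 months" operationalized as <= 92 calendar days
MIN_NORMAL_MEASUREMENTS = 9
MIN_PRE_DIAGNOSIS_MEASUREMENTS = 2

# exclusion-log reason codes
REASON_AKI = "aki"
REASON_EGFR_BELOW_60 = "egfr_below_60"
REASON_CKD_CODE = "ckd_code"
REASON_TOO_FEW = "too_few_measurements"
REASON_INITIAL_EGFR = "initial_egfr_below_60"
REASON_NO_PRE_DX = "no_pre_diagnosis_observations"


def code_matches(code: str, pattern: str) -> bool:
    """ICD code match: exact, or prefix when the pattern ends with ``*``."""
    code = code.strip().upper()
    pattern = pattern.strip().upper()
    if pattern.endswith("*"):
        return code.startswith(pattern[:-1])
    return code == pattern


def matches_any(code: str, patterns: Iterable[str]) -> bool:
    return any(code_matches(code, p) for p in patterns)


def assign_groups(
    patients: Sequence[RawPatient],
    eskd_codes: Sequence[str] = DEFAULT_ESKD_CODES,
) -> Dict[str, Optional[date]]:
    """Provisional labels: patient_id -> earliest ESKD diagnosis date, or None.

    A patient is ESKD-labeled iff any diagnosis code matches the ESKD list;
    the diagnosis date is the earliest date over matching codes.  An ESKD
    label without any dated matching code is a data error.
    """
    if not eskd_codes:
        raise InvalidInputError("ESKD code list must be non-empty")
    labels: Dict[str, Optional[date]] = {}
    for p in patients:
        match_dates = [
            d for _, code, d in p.diagnosis_codes if matches_any(code, eskd_codes)
        ]
        if not match_dates:
            labels[p.patient_id] = None
            continue
        dated = [d for d in match_dates if d is not None]
        if not dated:
            raise DataError(
                f"patient {p.patient_id}: ESKD code present but undated"
            )
        labels[p.patient_id] = min(dated)
    return labels


def is_aki(series: MeasurementSeries, window_days: int = AKI_WINDOW_DAYS) -> bool:
    """Acute presentation: every eGFR < 90 and the record spans <= window."""
    span = (series.dates[-1] - series.dates[0]).days
    return bool(np.all(series.egfr < 90.0)) and span <= window_days


def exclude_aki(
    series_list: Sequence[MeasurementSeries], window_days: int = AKI_WINDOW_DAYS
) -> Tuple[List[MeasurementSeries], Dict[str, str]]:
    """Split into retained series and an exclusion log of acute presentations."""
    kept, log = [], {}
    for s in series_list:
        if is_aki(s, window_days):
            log[s.patient_id] = REASON_AKI
        else:
            kept.append(s)
    return kept, log


def select_normal(
    series_list: Sequence[MeasurementSeries],
    patients_codes: Dict[str, list],
    ckd_exclusion_codes: Sequence[str] = DEFAULT_CKD_EXCLUSION_CODES,
    min_measurements: int = MIN_NORMAL_MEASUREMENTS,
) -> Tuple[List[MeasurementSeries], Dict[str, str]]:
    """Normal group: no CKD code, no eGFR < 60 anywhere, enough observations.

    ``patients_codes`` maps patient_id to their (version, code, date) tuples.
    """
    kept, log = [], {}
    for s in series_list:
        codes = patients_codes.get(s.patient_id, [])
        if any(matches_any(code, ckd_exclusion_codes) for _, code, _ in codes):
            log[s.patient_id] = REASON_CKD_CODE
        elif bool(np.any(s.egfr < 60.0)):
            log[s.patient_id] = REASON_EGFR_BELOW_60
        elif len(s) < min_measurements:
            log[s.patient_id] = REASON_TOO_FEW
        else:
            kept.append(s)
    return kept, log


def select_eskd(
    series_list: Sequence[MeasurementSeries],
    min_pre_diagnosis: int = MIN_PRE_DIAGNOSIS_MEASUREMENTS,
) -> Tuple[List[MeasurementSeries], Dict[str, str]]:
    """ESKD group: first eGFR >= 60 (boundary inclusive) and a usable pre-
    diagnosis record of at least ``min_pre_diagnosis`` observations."""
    kept, log = [], {}
    for s in series_list:
        if s.diagnosis_date is None:
            raise DataError(f"patient {s.patient_id}: ESKD series without diagnosis date")
        if s.egfr[0] < 60.0:
            log[s.patient_id] = REASON_INITIAL_EGFR
            continue
        pre = s.before(s.diagnosis_date)
        if pre is None or len(pre) < min_pre_diagnosis:
            log[s.patient_id] = REASON_NO_PRE_DX
            continue
        kept.append(s)
    return kept, log


def build_cohort(
    patients: Sequence[RawPatient],
    eskd_codes: Sequence[str] = DEFAULT_ESKD_CODES,
    ckd_exclusion_codes: Sequence[str] = DEFAULT_CKD_EXCLUSION_CODES,
    aki_window_days: int = AKI_WINDOW_DAYS,
    min_normal_measurements: int = MIN_NORMAL_MEASUREMENTS,
) -> LabeledCohort:
    """Apply the full selection flow to raw patients and label the survivors."""
    labels = assign_groups(patients, eskd_codes)
    series_list = [p.to_series(diagnosis_date=labels[p.patient_id]) for p in patients]
    series_list, log = exclude_aki(series_list, aki_window_days)

    eskd_candidates = [s for s in series_list if s.diagnosis_date is not None]
    other = [s for s in series_list if s.diagnosis_date is None]

    eskd, eskd_log = select_eskd(eskd_candidates)
    log.update(eskd_log)

    codes_by_id = {p.patient_id: p.diagnosis_codes for p in patients}
    normal, normal_log = select_normal(
        other, codes_by_id, ckd_exclusion_codes, min_normal_measurements
    )
    log.update(normal_log)
    return LabeledCohort(normal=normal, eskd=eskd, exclusion_log=log)


@dataclass
class KsResult:
    statistic: float
    pvalue: float
    reject: bool  # at the chosen significance level


def estimate_reference(
    normal_group: Sequence[MeasurementSeries],
    decline_rate: float = DEFAULT_DECLINE_RATE,
) -> NormalReference:
    """Estimate the healthy reference from the Normal group.

    Per-integer-age means are computed over all measurements taken at each
    age; sigma is the pooled within-age SD (the residual spread about the
    age-specific means, which is the scale on which the CUSUM standardizes
    deviations from the age-adjusted mean).  The overall mean's standard
    error treats the patient, not the measurement, as the sampling unit.
    """
    if not normal_group:
        raise InvalidInputError("normal group is empty")
    ages = np.concatenate([np.floor(s.ages).astype(int) for s in normal_group])
    egfr = np.concatenate([s.egfr for s in normal_group])

    mu0_by_age: Dict[int, float] = {}
    residual_ss = 0.0
    for a in np.unique(ages):
        vals = egfr[ages == a]
        mu0_by_age[int(a)] = float(vals.mean())
        residual_ss += float(((vals - vals.mean()) ** 2).sum())
    n_bins = len(mu0_by_age)
    if len(egfr) <= n_bins:
        raise InsufficientDataError("too few measurements to estimate a pooled SD")
    sigma = float(np.sqrt(residual_ss / (len(egfr) - n_bins)))
    if sigma <= 0:
        raise InvalidInputError("degenerate reference: pooled SD is zero")

    patient_means = np.array([float(s.egfr.mean()) for s in normal_group])
    if len(patient_means) > 1:
        overall_se = float(patient_means.std(ddof=1) / np.sqrt(len(patient_means)))
    else:
        overall_se = float("nan")
    return NormalReference(
        mu0_by_age=mu0_by_age,
        sigma=sigma,
        decline_rate=decline_rate,
        overall_mean=float(egfr.mean()),
        overall_se=overall_se,
    )


def ks_normality_check(values: Sequence[float], alpha: float = 0.05) -> KsResult:
    """One-sample Kolmogorov–Smirnov check of eGFR normality.

    Tests the values against a normal distribution with their estimated mean
    and SD; requires at least 20 values.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 20:
        raise InsufficientDataError("need >= 20 values for the KS check")
    sd = values.std(ddof=1)
    if sd == 0:
        raise InvalidInputError("degenerate sample: all values identical")
    stat, pvalue = stats.kstest(values, "norm", args=(values.mean(), sd))
    return KsResult(statistic=float(stat), pvalue=float(pvalue), reject=bool(pvalue < alpha))
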