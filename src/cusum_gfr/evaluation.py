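"""Scoring, (w, T) tuning by cross-validation, ROC, earliness and subgroups.

A patient in the ESKD group counts as a true positive only when the signal
occurs strictly before the diagnosis date (only pre-diagnosis observations
are scored, so any signal qualifies); an ESKD patient who never signals is a
false negative.  A Normal-group patient who signals is a false positive.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from ._exceptions import InsufficientDataError, InvalidInputError, UndefinedMetricError
from .cohort import estimate_reference
from .cusum import CusumParams, NormalReference, earliness, run_cusum
from .detector import CusumGfrDetector, _scoring_series
from .series import LabeledCohort, MeasurementSeries

DEFAULT_W_GRID = (0.25, 0.5, 0.75, 1.0, 1.25)
DEFAULT_T_GRID = (-6.0, -5.0, -4.0, -3.0, -2.0)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerformanceMetrics:
    sensitivity: float
    specificity: float
    accuracy: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass
class SignalRecord:
    """Per-patient outcome at a fixed (w, T)."""

    patient_id: str
    group: str  # "normal" | "eskd"
    signaled: bool
    signal_date: Optional[date] = None
    egfr_at_signal: Optional[float] = None
    earliness_days: Optional[int] = None
    pre_diagnosis: Optional[bool] = None
    outcome: str = ""  # tp | fp | tn | fn


@dataclass
class EarlinessSummary:
    mean_days: float
    se_days: float
    median_days: float
    n: int
    frac_egfr_ge_30: float
    frac_egfr_ge_45: float
    frac_egfr_ge_60: float


@dataclass
class TuningResult:
    """Cross-validated grid of (w, T) operating points and the chosen one."""

    grid: Dict[Tuple[float, float], PerformanceMetrics]
    best: Tuple[float, float]
    roc: List[Tuple[float, float]] = field(default_factory=list)  # (1-spec, sens)


def classify_cohort(
    cohort: LabeledCohort, ref: NormalReference, params: CusumParams
) -> Tuple[List[SignalRecord], ConfusionCounts]:
    """Score every patient and tally the confusion counts."""
    if ref.sigma <= 0:
        raise InvalidInputError("reference sigma must be positive")
    records: List[SignalRecord] = []
    counts = ConfusionCounts()
    for series in cohort.normal:
        trace = run_cusum(series, ref, params)
        rec = SignalRecord(series.patient_id, "normal", trace.signaled)
        if trace.signaled:
            rec.signal_date = trace.signal_date
            rec.egfr_at_signal = trace.egfr_at_signal
            rec.outcome = "fp"
            counts.fp += 1
        else:
            rec.outcome = "tn"
            counts.tn += 1
        records.append(rec)
    for series in cohort.eskd:
        scorable = _scoring_series(series)
        signaled = False
        rec = SignalRecord(series.patient_id, "eskd", False)
        if scorable is not None:
            trace = run_cusum(scorable, ref, params)
            if trace.signaled:
                signaled = True
                e = earliness(trace.signal_date, series.diagnosis_date)
                rec.signaled = True
                rec.signal_date = trace.signal_date
                rec.egfr_at_signal = trace.egfr_at_signal
                rec.earliness_days = e.days
                rec.pre_diagnosis = e.pre_diagnosis
        if signaled:
            rec.outcome = "tp"
            counts.tp += 1
        else:
            rec.outcome = "fn"
            counts.fn += 1
        records.append(rec)
    return records, counts


def metrics(counts: ConfusionCounts) -> PerformanceMetrics:
    """Sensitivity, specificity and accuracy from confusion counts."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise UndefinedMetricError(
            "both an ESKD and a Normal class are required to define the rates"
        )
    return PerformanceMetrics(
        sensitivity=counts.tp / (counts.tp + counts.fn),
        specificity=counts.tn / (counts.tn + counts.fp),
        accuracy=(counts.tp + counts.tn) / counts.total,
    )


def _patients_and_labels(cohort: LabeledCohort):
    X = np.empty(cohort.n_patients, dtype=object)
    y = np.empty(cohort.n_patients, dtype=int)
    for i, s in enumerate(cohort.normal):
        X[i], y[i] = s, 0
    for j, s in enumerate(cohort.eskd):
        X[len(cohort.normal) + j], y[len(cohort.normal) + j] = s, 1
    return X, y


def _counts_from_signals(signaled: np.ndarray, y: np.ndarray) -> ConfusionCounts:
    pos, neg = y == 1, y == 0
    return ConfusionCounts(
        tp=int(np.sum(signaled & pos)),
        fn=int(np.sum(~signaled & pos)),
        fp=int(np.sum(signaled & neg)),
        tn=int(np.sum(~signaled & neg)),
    )


def kfold_tune(
    cohort: LabeledCohort,
    w_grid: Sequence[float] = DEFAULT_W_GRID,
    T_grid: Sequence[float] = DEFAULT_T_GRID,
    k: int = 10,
    seed: int = 0,
    refit_reference: bool = True,
    reference: Optional[NormalReference] = None,
) -> TuningResult:
    """Choose (w, T) by stratified k-fold cross-validation.

    For each fold the healthy reference is re-estimated from the training
    normals (``refit_reference=True``, no leakage into the test fold) or the
    supplied/global reference is reused.  For each grid point the per-fold
    test metrics are averaged; the best point maximizes mean accuracy, ties
    broken by Youden's J (sensitivity + specificity − 1), then by larger |T|.
    """
    if not w_grid or not len(T_grid):
        raise InvalidInputError("w and T grids must be non-empty")
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    if len(cohort.normal) < k or len(cohort.eskd) < k:
        raise InvalidInputError("both groups need at least k patients")
    X, y = _patients_and_labels(cohort)
    if reference is None and not refit_reference:
        reference = estimate_reference(list(cohort.normal))

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: Dict[Tuple[float, float], list] = {
        (w, T): [] for w in w_grid for T in T_grid
    }
    for train_idx, test_idx in splitter.split(X, y):
        if refit_reference and reference is None:
            ref = estimate_reference([s for s in X[train_idx] if s.diagnosis_date is None])
        else:
            ref = reference
        for w in w_grid:
            det = CusumGfrDetector(w=w, T=0.0, reference=ref).fit(X[test_idx])
            scores = det.decision_function(X[test_idx])  # = -min trace value
            for T in T_grid:
                counts = _counts_from_signals(scores >= -T, y[test_idx])
                fold_metrics[(w, T)].append(metrics(counts))

    grid = {
        key: PerformanceMetrics(
            sensitivity=float(np.mean([m.sensitivity for m in ms])),
            specificity=float(np.mean([m.specificity for m in ms])),
            accuracy=float(np.mean([m.accuracy for m in ms])),
        )
        for key, ms in fold_metrics.items()
    }
    best = max(
        grid,
        key=lambda key: (grid[key].accuracy, grid[key].youden_j, abs(key[1])),
    )
    full_ref = reference if reference is not None else estimate_reference(list(cohort.normal))
    roc = roc_curve(cohort, full_ref, w=best[0], T_grid=T_grid)
    return TuningResult(grid=grid, best=best, roc=roc.points)


@dataclass
class RocResult:
    points: List[Tuple[float, float]]  # (1 - specificity, sensitivity), by T ascending
    thresholds: List[float]
    auc: Optional[float]


def roc_curve(
    cohort: LabeledCohort,
    ref: NormalReference,
    w: float,
    T_grid: Sequence[float],
) -> RocResult:
    """Operating points over a threshold grid at fixed w, with trapezoid AUC.

    As T rises toward 0 the detector signals more readily, so sensitivity is
    non-decreasing and specificity non-increasing along the returned points.
    AUC is anchored at (0,0) and (1,1); a single-threshold grid yields a
    single point and no AUC.
    """
    T_grid = sorted(T_grid)
    X, y = _patients_and_labels(cohort)
    det = CusumGfrDetector(w=w, T=0.0, reference=ref).fit(X)
    scores = det.decision_function(X)
    points = []
    for T in T_grid:
        m = metrics(_counts_from_signals(scores >= -T, y))
        points.append((1.0 - m.specificity, m.sensitivity))
    if len(set(T_grid)) < 2:
        return RocResult(points=points, thresholds=list(T_grid), auc=None)
    xs = np.array([0.0] + [p[0] for p in points] + [1.0])
    ys = np.array([0.0] + [p[1] for p in points] + [1.0])
    order = np.lexsort((ys, xs))
    auc = float(np.trapezoid(ys[order], xs[order]))
    return RocResult(points=points, thresholds=list(T_grid), auc=auc)


def earliness_summary(records: Sequence[SignalRecord]) -> EarlinessSummary:
    """Summaries over true positives whose signal preceded diagnosis."""
    qualifying = [
        r
        for r in records
        if r.group == "eskd" and r.signaled and r.earliness_days is not None and r.earliness_days > 0
    ]
    if not qualifying:
        raise InsufficientDataError("no true positives with a pre-diagnosis signal")
    days = np.array([r.earliness_days for r in qualifying], dtype=float)
    egfr = np.array([r.egfr_at_signal for r in qualifying], dtype=float)
    se = float(days.std(ddof=1) / np.sqrt(len(days))) if len(days) > 1 else float("nan")
    return EarlinessSummary(
        mean_days=float(days.mean()),
        se_days=se,
        median_days=float(np.median(days)),
        n=len(days),
        frac_egfr_ge_30=float(np.mean(egfr >= 30.0)),
        frac_egfr_ge_45=float(np.mean(egfr >= 45.0)),
        frac_egfr_ge_60=float(np.mean(egfr >= 60.0)),
    )


KNOWN_STRATIFIERS = (
    "age_band",
    "sex",
    "race",
    "hypertension",
    "diabetes",
    "cardiovascular",
    "hypercholesterolemia",
)


def _level_of(series: MeasurementSeries, stratifier: str):
    if stratifier == "sex":
        return series.sex
    if stratifier == "race":
        return series.race if series.race is not None else "unknown"
    if stratifier == "age_band":
        return "65_and_over" if series.age_at_entry >= 65 else "under_65"
    return bool(series.flags.get(stratifier, False))


def subgroup_performance(
    cohort: LabeledCohort,
    records: Sequence[SignalRecord],
    stratifier: str,
) -> pd.DataFrame:
    """Per-subgroup metrics and earliness, with Welch comparisons of earliness.

    With two levels a single Welch two-sample t comparison is reported on
    both rows; with more, each level is compared against the rest.  Levels
    with no ESKD patient have the rate metrics flagged undefined (NaN).
    """
    if stratifier not in KNOWN_STRATIFIERS:
        raise InvalidInputError(f"unknown stratifier {stratifier!r}")
    level_by_id = {
        s.patient_id: _level_of(s, stratifier)
        for s in list(cohort.normal) + list(cohort.eskd)
    }
    by_level: Dict[object, List[SignalRecord]] = {}
    for r in records:
        by_level.setdefault(level_by_id[r.patient_id], []).append(r)

    levels = sorted(by_level, key=str)
    earliness_by_level = {
        lv: [
            r.earliness_days
            for r in recs
            if r.outcome == "tp" and r.earliness_days is not None and r.earliness_days > 0
        ]
        for lv, recs in by_level.items()
    }
    rows = []
    for lv in levels:
        recs = by_level[lv]
        counts = ConfusionCounts(
            tp=sum(r.outcome == "tp" for r in recs),
            fp=sum(r.outcome == "fp" for r in recs),
            tn=sum(r.outcome == "tn" for r in recs),
            fn=sum(r.outcome == "fn" for r in recs),
        )
        try:
            m = metrics(counts)
            sens, spec, acc = m.sensitivity, m.specificity, m.accuracy
            defined = True
        except UndefinedMetricError:
            sens = spec = acc = float("nan")
            defined = False
        own = earliness_by_level[lv]
        if len(levels) == 2:
            other = earliness_by_level[levels[0] if lv == levels[1] else levels[1]]
        else:
            other = [d for o, ds in earliness_by_level.items() if o != lv for d in ds]
        if len(own) >= 2 and len(other) >= 2:
            t, p = stats.ttest_ind(own, other, equal_var=False)
        else:
            t, p = float("nan"), float("nan")
        rows.append(
            {
                "level": lv,
                "n_patients": len(recs),
                "n_eskd": counts.tp + counts.fn,
                "sensitivity": sens,
                "specificity": spec,
                "accuracy": acc,
                "defined": defined,
                "mean_earliness_days": float(np.mean(own)) if own else float("nan"),
                "n_true_positive": len(own),
                "welch_t": float(t),
                "welch_p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("level")
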