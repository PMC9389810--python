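"""Scikit-learn style estimator wrapping the CUSUM monitor.

``CusumGfrDetector`` is a binary classifier over patients: X is a sequence of
:class:`~cusum_gfr.series.MeasurementSeries` and y labels each patient 0
(healthy reference group) or 1 (progressed to end-stage kidney disease).
``fit`` estimates the healthy reference (per-age means, pooled within-age SD)
from the y == 0 patients; ``predict`` flags a patient when their CUSUM trace
ever reaches the threshold T.  For patients with a diagnosis date only
observations strictly before diagnosis are scored, so a positive prediction
is always a pre-diagnosis signal.

The estimator composes with scikit-learn model selection (X can be a numpy
object array), which the grid-tuning helper in :mod:`cusum_gfr.evaluation`
exploits.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._exceptions import InvalidInputError
from .cohort import estimate_reference
from .cusum import CusumParams, CusumTrace, NormalReference, run_cusum
from .series import MeasurementSeries


def _scoring_series(series: MeasurementSeries) -> Optional[MeasurementSeries]:
    """The part of a series that may be scored: pre-diagnosis only, if dated."""
    if series.diagnosis_date is None:
        return series
    return series.before(series.diagnosis_date)


class CusumGfrDetector(BaseEstimator, ClassifierMixin):
    """Flag patients whose eGFR series shows a sustained decline.

    Parameters
    ----------
    w : float
        Per-observation allowance (in units of the reference SD) for benign
        shifts; larger w tolerates more decline before accumulating.
    T : float
        Non-positive signal threshold; the patient is flagged at the first
        observation where the CUSUM value is <= T.
    decline_rate : float
        Annual healthy eGFR decline used for age adjustment,
        mL/min/1.73 m² per year.
    reference : NormalReference, optional
        Pre-computed healthy reference.  When given, ``fit`` uses it as-is
        (y may then be omitted); otherwise the reference is estimated from
        the y == 0 patients.

    Attributes
    ----------
    reference_ : NormalReference
        The healthy reference used for scoring.
    classes_ : ndarray
        ``[0, 1]``.
    """

    def __init__(
        self,
        w: float = 0.75,
        T: float = -4.0,
        decline_rate: float = 0.81,
        reference: Optional[NormalReference] = None,
    ):
        self.w = w
        self.T = T
        self.decline_rate = decline_rate
        self.reference = reference

    def fit(self, X: Sequence[MeasurementSeries], y=None) -> "CusumGfrDetector":
        CusumParams(w=self.w, T=self.T)  # validate the pair
        if self.reference is not None:
            self.reference_ = self.reference
        else:
            if y is None:
                raise InvalidInputError(
                    "y is required to identify reference patients when no "
                    "pre-computed reference is supplied"
                )
            y = np.asarray(y)
            if len(y) != len(X):
                raise InvalidInputError("X and y differ in length")
            normals = [s for s, label in zip(X, y) if label == 0]
            self.reference_ = estimate_reference(normals, decline_rate=self.decline_rate)
        self.classes_ = np.array([0, 1])
        return self

    def trace(self, series: MeasurementSeries) -> CusumTrace:
        """Full CUSUM trace for one patient's scorable observations."""
        check_is_fitted(self, "reference_")
        scorable = _scoring_series(series)
        if scorable is None:
            return CusumTrace(values=np.array([]))
        return run_cusum(scorable, self.reference_, CusumParams(w=self.w, T=self.T))

    def decision_function(self, X: Sequence[MeasurementSeries]) -> np.ndarray:
        """Per-patient abnormality score: minus the minimum trace value.

        Higher scores mean stronger evidence of decline; ``predict`` flags
        score >= −T.  Patients with no scorable observations get −inf.
        """
        check_is_fitted(self, "reference_")
        scores = np.empty(len(X))
        for i, series in enumerate(X):
            t = self.trace(series)
            scores[i] = -t.values.min() if len(t.values) else -np.inf
        return scores

    def predict(self, X: Sequence[MeasurementSeries]) -> np.ndarray:
        return (self.decision_function(X) >= -self.T).astype(int)
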