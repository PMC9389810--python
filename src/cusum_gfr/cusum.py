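"""The age-adjusted CUSUM statistic over serial eGFR.

For patient observations eGFR_1, eGFR_2, ... the statistic accumulates
standardized downward deviations from an age-adjusted reference mean:

    C_0 = 0
    C_i = min(0, (eGFR_i − μ̂_i)/σ̂ + w + C_{i−1})

where μ̂_i = μ̂_0 − d·Δt_i is the healthy-population mean eGFR at the patient's
age (μ̂_0 looked up at the integer age of the first measurement, d the annual
healthy decline, default 0.81 mL/min/1.73 m²/yr, Δt_i the years elapsed since
the first measurement), σ̂ the pooled within-age SD of the healthy group, and
w >= 0 a per-observation allowance for benign shifts.  The min operator caps
the statistic at zero so only sustained declines accumulate.  The patient
signals at the first observation where C_i <= T for a non-positive threshold T
(inclusive boundary).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Dict, NamedTuple, Optional, Sequence

import numpy as np

from ._exceptions import InvalidInputError
from .series import MeasurementSeries

DEFAULT_DECLINE_RATE = 0.81  # mL/min/1.73 m² per year, healthy population


@dataclass
class NormalReference:
    """Healthy-population reference for standardizing eGFR deviations.

    Attributes
    ----------
    mu0_by_age : dict
        Mean eGFR (mL/min/1.73 m²) per integer age; ages missing from the
        table fall back to ``overall_mean``.
    sigma : float
        Pooled within-age SD of eGFR (mL/min/1.73 m²); must be positive.
    decline_rate : float
        Annual healthy eGFR decline, mL/min/1.73 m² per year.
    overall_mean, overall_se : float
        Mean eGFR over all reference measurements and its patient-level
        standard error.
    """

    mu0_by_age: Dict[int, float]
    sigma: float
    decline_rate: float = DEFAULT_DECLINE_RATE
    overall_mean: float = float("nan")
    overall_se: float = float("nan")

    def __post_init__(self):
        if not self.sigma > 0:
            raise InvalidInputError("reference sigma must be positive")
        if self.decline_rate < 0:
            raise InvalidInputError("decline rate must be non-negative")
        if any(v <= 0 for v in self.mu0_by_age.values()):
            raise InvalidInputError("per-age mean eGFR values must be positive")

    def mu0(self, age_years: float) -> float:
        """Reference mean at the integer age of the first measurement."""
        return self.mu0_by_age.get(int(np.floor(age_years)), self.overall_mean)


@dataclass(frozen=True)
class CusumParams:
    """Tuning pair: allowance w >= 0 and non-positive signal threshold T."""

    w: float = 0.75
    T: float = -4.0

    def __post_init__(self):
        if not (self.T <= 0 <= self.w):
            raise InvalidInputError(f"need T <= 0 <= w, got w={self.w}, T={self.T}")


@dataclass
class CusumTrace:
    """Per-observation CUSUM values plus the first signal, if any."""

    values: np.ndarray
    signal_index: Optional[int] = None
    signal_date: Optional[date] = None
    egfr_at_signal: Optional[float] = None

    @property
    def signaled(self) -> bool:
        return self.signal_index is not None


class Earliness(NamedTuple):
    """Calendar days from signal to diagnosis; positive = signal came first."""

    days: int
    pre_diagnosis: bool


def age_adjusted_mean(ref: NormalReference, mu0: float, delta_t: float) -> float:
    """Reference mean μ̂_i = μ̂_0 − d·Δt after ``delta_t`` years of follow-up."""
    if delta_t < 0:
        raise InvalidInputError("delta_t must be >= 0 (observations are ordered)")
    return mu0 - ref.decline_rate * delta_t


def cusum_step(prev: float, egfr: float, mu_i: float, sigma: float, w: float) -> float:
    """One recursion step: min(0, (egfr − mu_i)/sigma + w + prev)."""
    if sigma <= 0:
        raise InvalidInputError("sigma must be positive")
    if prev > 0:
        raise InvalidInputError("previous CUSUM value must be <= 0")
    return min(0.0, (egfr - mu_i) / sigma + w + prev)


def run_cusum(
    series: MeasurementSeries, ref: NormalReference, params: CusumParams
) -> CusumTrace:
    """Run the recursion over a patient's series and locate the first signal.

    The state is never reset after a signal; values continue to be computed
    and only the first threshold crossing is reported.
    """
    if len(series) == 0:
        raise InvalidInputError("empty measurement series")
    mu0 = ref.mu0(series.age_at_entry)
    if not np.isfinite(mu0):
        raise InvalidInputError(
            "reference covers neither the patient's entry age nor a pooled mean"
        )
    values = cusum_values(series.egfr, series.elapsed_years, mu0, ref, params.w)
    idx = detect_signal(values, params.T)
    trace = CusumTrace(values=values)
    if idx is not None:
        trace.signal_index = idx
        trace.signal_date = series.dates[idx]
        trace.egfr_at_signal = float(series.egfr[idx])
    return trace


def cusum_values(
    egfr: Sequence[float],
    elapsed_years: Sequence[float],
    mu0: float,
    ref: NormalReference,
    w: float,
) -> np.ndarray:
    """Vector of CUSUM values for precomputed eGFR / elapsed-time arrays."""
    egfr = np.asarray(egfr, dtype=float)
    # deviations from the age-adjusted mean, standardized, plus the allowance
    increments = (egfr - (mu0 - ref.decline_rate * np.asarray(elapsed_years))) / ref.sigma + w
    values = np.empty_like(increments)
    prev = 0.0
    for i, inc in enumerate(increments):
        prev = min(0.0, inc + prev)
        values[i] = prev
    return values


def detect_signal(values: Sequence[float], T: float) -> Optional[int]:
    """First index with value <= T (inclusive boundary), or None."""
    if T > 0:
        raise InvalidInputError("threshold T must be <= 0")
    below = np.asarray(values, dtype=float) <= T
    if not below.any():
        return None
    return int(np.argmax(below))


def earliness(signal_date: date, diagnosis_date: date) -> Earliness:
    """Days from signal to diagnosis; flagged not-early when non-positive."""
    days = (diagnosis_date - signal_date).days
    return Earliness(days=days, pre_diagnosis=days > 0)
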