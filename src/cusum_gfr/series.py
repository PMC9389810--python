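"""In-memory containers for longitudinal patient data."""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

import numpy as np

from ._exceptions import InvalidInputError
from .egfr import ckd_epi_2021

DAYS_PER_YEAR = 365.25  # actual/365.25 calendar basis for fractional years


def years_between(start: date, end: date) -> float:
    """Fractional years from ``start`` to ``end`` on an actual/365.25 basis."""
    return (end - start).days / DAYS_PER_YEAR


@dataclass
class MeasurementSeries:
    """One patient's time-ordered serum-creatinine/eGFR observations.

    ``egfr`` is derived from creatinine via the 2021 CKD-EPI equation when not
    supplied.  Dates must be strictly increasing. ``diagnosis_date`` is set for
    patients with a dated end-stage kidney disease code, ``None`` otherwise.
    """

    patient_id: str
    sex: str
    birth_date: date
    dates: Sequence[date]
    scr: Sequence[float]
    egfr: Optional[Sequence[float]] = None
    diagnosis_date: Optional[date] = None
    race: Optional[str] = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dates = list(self.dates)
        self.scr = np.asarray(self.scr, dtype=float)
        if len(self.dates) == 0:
            raise InvalidInputError("a measurement series needs >= 1 observation")
        if len(self.dates) != len(self.scr):
            raise InvalidInputError("dates and creatinine values differ in length")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise InvalidInputError(
                f"observation dates must be strictly increasing ({self.patient_id})"
            )
        if self.egfr is None:
            self.egfr = ckd_epi_2021(self.scr, self.ages, self.sex)
        else:
            self.egfr = np.asarray(self.egfr, dtype=float)
            if len(self.egfr) != len(self.scr):
                raise InvalidInputError("egfr and creatinine values differ in length")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def ages(self) -> np.ndarray:
        """Fractional age in years at each observation date."""
        return np.array([years_between(self.birth_date, d) for d in self.dates])

    @property
    def age_at_entry(self) -> float:
        return years_between(self.birth_date, self.dates[0])

    @property
    def elapsed_years(self) -> np.ndarray:
        """Years since the first observation, per observation."""
        first = self.dates[0]
        return np.array([years_between(first, d) for d in self.dates])

    def before(self, cutoff: date) -> Optional["MeasurementSeries"]:
        """Sub-series of observations strictly before ``cutoff`` (None if empty)."""
        keep = [i for i, d in enumerate(self.dates) if d < cutoff]
        if not keep:
            return None
        return MeasurementSeries(
            patient_id=self.patient_id,
            sex=self.sex,
            birth_date=self.birth_date,
            dates=[self.dates[i] for i in keep],
            scr=self.scr[keep],
            egfr=self.egfr[keep],
            diagnosis_date=self.diagnosis_date,
            race=self.race,
            flags=self.flags,
        )


@dataclass
class RawPatient:
    """A patient as read from the delimited input tables, before selection."""

    patient_id: str
    sex: str
    birth_date: date
    observations: list  # list of (date, scr_mg_dl), sortable by date
    diagnosis_codes: list = field(default_factory=list)  # (icd_version, code, date|None)
    flags: dict = field(default_factory=dict)
    race: Optional[str] = None

    def to_series(self, diagnosis_date: Optional[date] = None) -> MeasurementSeries:
        obs = sorted(self.observations, key=lambda o: o[0])
        return MeasurementSeries(
            patient_id=self.patient_id,
            sex=self.sex,
            birth_date=self.birth_date,
            dates=[d for d, _ in obs],
            scr=[s for _, s in obs],
            diagnosis_date=diagnosis_date,
            race=self.race,
            flags=dict(self.flags),
        )


@dataclass
class LabeledCohort:
    """Patients retained by the selection rules, split into two groups.

    ``normal`` and ``eskd`` are mutually exclusive; every excluded patient has
    a reason code in ``exclusion_log`` (patient_id -> reason).
    """

    normal: list
    eskd: list  # MeasurementSeries with diagnosis_date set
    exclusion_log: dict = field(default_factory=dict)

    def __post_init__(self):
        overlap = {s.patient_id for s in self.normal} & {s.patient_id for s in self.eskd}
        if overlap:
            raise InvalidInputError(f"groups must be mutually exclusive: {overlap}")

    @property
    def n_patients(self) -> int:
        return len(self.normal) + len(self.eskd)
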