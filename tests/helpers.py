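"""Shared helpers for constructing hand-made series in tests."""
from datetime import date, timedelta

import numpy as np

from cusum_gfr.egfr import invert_ckd_epi
from cusum_gfr.series import MeasurementSeries, years_between


def make_series(egfr_values, patient_id="p1", sex="male", start=date(2015, 1, 1),
                gap_days=30, birth_date=date(1965, 1, 1)):
    """Series with prescribed eGFR values at regular gaps (creatinine implied)."""
    dates = [start + timedelta(days=i * gap_days) for i in range(len(egfr_values))]
    scr = [
        invert_ckd_epi(g, years_between(birth_date, d), sex)
        for g, d in zip(egfr_values, dates)
    ]
    return MeasurementSeries(
        patient_id=patient_id, sex=sex, birth_date=birth_date,
        dates=dates, scr=scr, egfr=np.asarray(egfr_values, dtype=float),
    )
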