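"""The 2021 CKD-EPI creatinine equation (race-free refit) and its inverse.

The forward map converts serum creatinine (mg/dL), age (years) and sex into an
estimated glomerular filtration rate in mL/min/1.73 m²:

    eGFR = 142 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^(−1.200) · 0.9938^age · s

with κ = 0.7 (female) / 0.9 (male), α = −0.241 (female) / −0.302 (male) and
s = 1.012 for females, 1 for males.  The map is strictly decreasing in
creatinine and in age, and continuous at the knot Scr = κ.

The inverse solves each power-law branch in closed form; it is used by the
cohort simulator so that synthetic patients are emitted as creatinine values
and the full creatinine → eGFR pipeline is exercised.
"""
from __future__ import annotations

import warnings

import numpy as np

from ._exceptions import DomainError, InvalidInputError

SCALE = 142.0
AGE_FACTOR = 0.9938
EXPONENT_ABOVE_KNOT = -1.200
KAPPA = {"female": 0.7, "male": 0.9}
ALPHA = {"female": -0.241, "male": -0.302}
SEX_MULTIPLIER = {"female": 1.012, "male": 1.0}

#: creatinine values above this are passed through with a warning, not censored
SCR_WARN_LIMIT = 20.0
#: physiologic creatinine floor defining the attainable eGFR range of the inverse
SCR_FLOOR = 0.05

MIN_ADULT_AGE = 18.0


def _check_sex(sex: str) -> str:
    s = str(sex).lower()
    if s not in KAPPA:
        raise InvalidInputError(f"sex must be 'female' or 'male', got {sex!r}")
    return s


def ckd_epi_2021(scr, age, sex):
    """Estimated GFR (mL/min/1.73 m²) from serum creatinine, age and sex.

    Parameters
    ----------
    scr : float or array-like
        Serum creatinine in mg/dL; must be strictly positive.
    age : float or array-like
        Age in years at the measurement; adult equation, so age >= 18.
    sex : {"female", "male"}

    Returns
    -------
    float or ndarray
        eGFR in mL/min/1.73 m², same shape as the broadcast inputs.
    """
    sex = _check_sex(sex)
    scr_arr = np.asarray(scr, dtype=float)
    age_arr = np.asarray(age, dtype=float)
    if np.any(scr_arr <= 0):
        raise InvalidInputError("serum creatinine must be positive (mg/dL)")
    if np.any(age_arr < MIN_ADULT_AGE):
        raise InvalidInputError("adult equation only: age must be >= 18 years")
    if np.any(scr_arr > SCR_WARN_LIMIT):
        warnings.warn(
            f"creatinine above {SCR_WARN_LIMIT} mg/dL is non-physiologic; "
            "passing through uncensored",
            stacklevel=2,
        )
    kappa = KAPPA[sex]
    ratio = scr_arr / kappa
    egfr = (
        SCALE
        * np.minimum(ratio, 1.0) ** ALPHA[sex]
        * np.maximum(ratio, 1.0) ** EXPONENT_ABOVE_KNOT
        * AGE_FACTOR**age_arr
        * SEX_MULTIPLIER[sex]
    )
    if np.isscalar(scr) and np.isscalar(age):
        return float(egfr)
    return egfr


def egfr_at_knot(age: float, sex: str) -> float:
    """eGFR at scr = κ, where both power terms equal one."""
    sex = _check_sex(sex)
    return SCALE * AGE_FACTOR**age * SEX_MULTIPLIER[sex]


def max_attainable_egfr(age: float, sex: str) -> float:
    """Largest eGFR the inverse will accept, at the creatinine floor."""
    return float(ckd_epi_2021(SCR_FLOOR, age, sex))


def invert_ckd_epi(egfr: float, age: float, sex: str) -> float:
    """Serum creatinine (mg/dL) that yields ``egfr`` for this age and sex.

    Solves the piecewise power equation analytically on the branch consistent
    with scr ≶ κ, so the round trip through :func:`ckd_epi_2021` is exact to
    floating-point precision.  Targets above the value at the physiologic
    creatinine floor (0.05 mg/dL), or non-positive targets, raise
    :class:`DomainError`.
    """
    sex = _check_sex(sex)
    if np.asarray(age, dtype=float) < MIN_ADULT_AGE:
        raise InvalidInputError("adult equation only: age must be >= 18 years")
    egfr = float(egfr)
    if egfr <= 0:
        raise DomainError("target eGFR must be positive")
    if egfr > max_attainable_egfr(age, sex):
        raise DomainError(
            f"target eGFR {egfr} exceeds the attainable range for "
            f"age={age}, sex={sex}"
        )
    kappa = KAPPA[sex]
    at_knot = egfr_at_knot(age, sex)
    if egfr == at_knot:
        return kappa
    if egfr < at_knot:
        # scr > kappa branch: egfr = at_knot * (scr/kappa)^(-1.2)
        return kappa * (egfr / at_knot) ** (1.0 / EXPONENT_ABOVE_KNOT)
    # scr < kappa branch: egfr = at_knot * (scr/kappa)^alpha, alpha < 0
    return kappa * (egfr / at_knot) ** (1.0 / ALPHA[sex])
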