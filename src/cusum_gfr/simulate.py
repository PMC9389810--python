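"""Seeded generator of synthetic longitudinal kidney-function cohorts.

The generator emulates the statistical structure an EHR-based eGFR monitor
sees, so the whole pipeline is testable without real patient data:

* healthy patients whose latent eGFR declines 0.81 mL/min/1.73 m²/yr from an
  age-anchored entry mean (85.07 at age 64.5 by default) with independent
  Gaussian visit noise (SD 7.8) and no value below 60 (redraw);
* progressors whose latent trajectory is a mix of shapes — rapid drop after
  a change point, steady steep linear decline, or convex exponential decay —
  reaching a diagnosis threshold (eGFR 15) that defines the end-stage
  diagnosis date; the first observation is at least 60;
* irregular visit gaps drawn from a dispersed gamma (mean ~120 days);
* demographics and comorbidity flags sampled per group from configurable
  prevalences;
* optional decoy patients, each violating exactly one selection rule, so the
  cohort builder's exclusion log can be checked against ground truth.

Observations are emitted as serum creatinine (by inverting the 2021 CKD-EPI
equation at the visit age), so downstream code exercises the full
creatinine → eGFR path.  All randomness flows from ``SimConfig.seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._exceptions import SimConfigError
from .cohort import (
    REASON_AKI,
    REASON_CKD_CODE,
    REASON_EGFR_BELOW_60,
    REASON_INITIAL_EGFR,
    REASON_NO_PRE_DX,
    REASON_TOO_FEW,
)
from .egfr import invert_ckd_epi
from .series import DAYS_PER_YEAR, LabeledCohort, MeasurementSeries, RawPatient

TRAJECTORY_SHAPES = ("rapid", "slow_linear", "nonlinear")


def _prevalences() -> Dict[str, Tuple[float, float]]:
    # (normal, progressor) prevalences, anchored to the reference cohort table
    return {
        "hypertension": (0.54, 0.89),
        "diabetes": (0.26, 0.63),
        "cardiovascular": (0.15, 0.43),
        "hypercholesterolemia": (0.57, 0.63),
        "smoking": (0.18, 0.45),
    }


def _race_probs() -> Dict[str, Tuple[float, float]]:
    return {"white": (0.81, 0.67), "black": (0.07, 0.21), "other": (0.12, 0.12)}


@dataclass
class SimConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    n_normal: int = 200
    n_progressor: int = 50
    seed: int = 0

    # demographics
    entry_age_mean_normal: float = 64.5
    entry_age_mean_progressor: float = 57.9
    entry_age_sd: float = 10.0
    entry_age_range: Tuple[float, float] = (40.0, 80.0)
    female_prob: Tuple[float, float] = (0.54, 0.44)
    race_probs: Dict[str, Tuple[float, float]] = field(default_factory=_race_probs)
    comorbidity_prevalence: Dict[str, Tuple[float, float]] = field(
        default_factory=_prevalences
    )

    # healthy trajectory: mean eGFR at the anchor age, annual decline, SD
    normal_mean_anchor: float = 85.07
    anchor_age: float = 64.5
    normal_sd: float = 7.8
    normal_decline: float = 0.81
    followup_years: float = 5.0
    min_visits_normal: int = 9
    ar1_rho: float = 0.0  # optional AR(1) visit-noise correlation

    # visit schedule
    visit_gap_mean_days: float = 120.0
    visit_gap_shape: float = 1.5
    min_gap_days: int = 7
    entry_date_start: date = date(2012, 1, 1)
    entry_date_spread_days: int = 1096

    # progressor trajectories
    trajectory_mix: Tuple[float, float, float] = (0.35, 0.40, 0.25)
    entry_egfr_range: Tuple[float, float] = (70.0, 100.0)
    rapid_changepoint_years: Tuple[float, float] = (0.5, 3.0)
    rapid_slope_range: Tuple[float, float] = (10.0, 25.0)
    slow_slope_range: Tuple[float, float] = (6.0, 12.0)
    nonlinear_rate_range: Tuple[float, float] = (0.25, 0.5)
    diagnosis_threshold: float = 15.0
    min_years_to_diagnosis: float = 1.0
    max_years_to_diagnosis: float = 12.0
    post_diagnosis_visits: int = 2

    # decoys violating the selection rules, for exclusion-log checks
    decoys: bool = False
    n_decoys_per_rule: int = 3

    def __post_init__(self):
        if abs(sum(self.trajectory_mix) - 1.0) > 1e-9:
            raise SimConfigError("trajectory mix proportions must sum to 1")
        if self.normal_sd < 0 or self.visit_gap_mean_days <= 0:
            raise SimConfigError("scales must be positive")

    def entry_mean(self, age: float) -> float:
        """Healthy mean eGFR at entry for a given age."""
        return self.normal_mean_anchor + self.normal_decline * (self.anchor_age - age)


@dataclass
class SimulatedCohort:
    """Generator output: intended cohort, raw tables, and ground truth."""

    cohort: LabeledCohort
    raw_patients: List[RawPatient]
    ground_truth: pd.DataFrame  # patient_id, role, expected_group, expected_reason


# ---------------------------------------------------------------- internals


def _draw_age(cfg: SimConfig, rng: np.random.Generator, mean: float) -> float:
    lo, hi = cfg.entry_age_range
    for _ in range(1000):
        a = rng.normal(mean, cfg.entry_age_sd)
        if lo <= a <= hi:
            return float(a)
    raise SimConfigError("entry-age distribution incompatible with its range")


def _visit_times(
    cfg: SimConfig, rng: np.random.Generator, span_years: float, min_visits: int
) -> np.ndarray:
    """Visit times in years: 0, then dispersed gamma gaps, covering the span."""
    scale = cfg.visit_gap_mean_days / cfg.visit_gap_shape
    times = [0.0]
    while times[-1] < span_years or len(times) < min_visits:
        gap_days = max(cfg.min_gap_days, rng.gamma(cfg.visit_gap_shape, scale))
        times.append(times[-1] + gap_days / DAYS_PER_YEAR)
    return np.asarray(times)


def _noise(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    eps = rng.normal(0.0, cfg.normal_sd, size=n)
    if cfg.ar1_rho:
        rho = cfg.ar1_rho
        out = np.empty(n)
        out[0] = eps[0]
        for i in range(1, n):
            out[i] = rho * out[i - 1] + np.sqrt(1 - rho**2) * eps[i]
        return out
    return eps


def _demographics(cfg: SimConfig, rng: np.random.Generator, group: int):
    """group: 0 normal, 1 progressor."""
    sex = "female" if rng.random() < cfg.female_prob[group] else "male"
    races = list(cfg.race_probs)
    probs = np.array([cfg.race_probs[r][group] for r in races], dtype=float)
    race = races[rng.choice(len(races), p=probs / probs.sum())]
    flags = {
        name: bool(rng.random() < prev[group])
        for name, prev in cfg.comorbidity_prevalence.items()
    }
    return sex, race, flags


def _entry_date(cfg: SimConfig, rng: np.random.Generator) -> date:
    return cfg.entry_date_start + timedelta(
        days=int(rng.integers(0, cfg.entry_date_spread_days))
    )


def _series_from_latent(
    cfg: SimConfig,
    rng: np.random.Generator,
    patient_id: str,
    group: int,
    age0: float,
    times: np.ndarray,
    latent: np.ndarray,
    floor: float,
    first_at_least: Optional[float] = None,
) -> MeasurementSeries:
    """Observe a latent trajectory with noise and emit a creatinine series."""
    sex, race, flags = _demographics(cfg, rng, group)
    entry = _entry_date(cfg, rng)
    birth = entry - timedelta(days=round(age0 * DAYS_PER_YEAR))
    obs = latent + _noise(cfg, rng, len(times))
    for i in range(len(obs)):
        lo = first_at_least if (i == 0 and first_at_least is not None) else floor
        tries = 0
        while obs[i] < lo:
            obs[i] = latent[i] + rng.normal(0.0, cfg.normal_sd) if cfg.normal_sd > 0 else lo
            tries += 1
            if tries > 1000:
                raise SimConfigError(
                    f"cannot draw an observation >= {lo} around latent {latent[i]:.1f}"
                )
    dates = [entry + timedelta(days=round(t * DAYS_PER_YEAR)) for t in times]
    ages = age0 + times
    scr = np.array([invert_ckd_epi(g, a, sex) for g, a in zip(obs, ages)])
    return MeasurementSeries(
        patient_id=patient_id,
        sex=sex,
        birth_date=birth,
        dates=dates,
        scr=scr,
        race=race,
        flags=flags,
    )


def simulate_normal_patient(
    cfg: SimConfig, rng: np.random.Generator, patient_id: str = "N0"
) -> MeasurementSeries:
    """One healthy patient: age-declining latent mean, noise, no value < 60."""
    age0 = _draw_age(cfg, rng, cfg.entry_age_mean_normal)
    mu_entry = cfg.entry_mean(age0)
    if mu_entry - cfg.normal_decline * cfg.followup_years <= 60.0 + 1.0:
        raise SimConfigError(
            f"entry mean {mu_entry:.1f} at age {age0:.0f} too close to 60 to "
            "sustain a healthy series"
        )
    times = _visit_times(cfg, rng, cfg.followup_years, cfg.min_visits_normal)
    latent = mu_entry - cfg.normal_decline * times
    return _series_from_latent(
        cfg, rng, patient_id, group=0, age0=age0, times=times, latent=latent, floor=60.0
    )


def _sample_trajectory(
    cfg: SimConfig, rng: np.random.Generator
) -> Tuple[str, Callable[[np.ndarray], np.ndarray], float]:
    """Sampled latent shape, its function of time, and the years to diagnosis."""
    shape = TRAJECTORY_SHAPES[rng.choice(3, p=np.asarray(cfg.trajectory_mix))]
    e0 = rng.uniform(*cfg.entry_egfr_range)
    thr = cfg.diagnosis_threshold
    for _ in range(200):
        if shape == "rapid":
            tc = rng.uniform(*cfg.rapid_changepoint_years)
            s = rng.uniform(*cfg.rapid_slope_range)
            if s <= 0:
                continue
            t_d = tc + (e0 - cfg.normal_decline * tc - thr) / s

            def latent(t, e0=e0, tc=tc, s=s):
                pre = e0 - cfg.normal_decline * t
                post = e0 - cfg.normal_decline * tc - s * (t - tc)
                return np.where(t < tc, pre, post)

        elif shape == "slow_linear":
            s = rng.uniform(*cfg.slow_slope_range)
            if s <= 0:
                continue
            t_d = (e0 - thr) / s

            def latent(t, e0=e0, s=s):
                return e0 - s * t

        else:  # nonlinear convex decay
            r = rng.uniform(*cfg.nonlinear_rate_range)
            if r <= 0:
                continue
            t_d = np.log(e0 / thr) / r

            def latent(t, e0=e0, r=r):
                return e0 * np.exp(-r * t)

        if cfg.min_years_to_diagnosis <= t_d <= cfg.max_years_to_diagnosis:
            return shape, latent, float(t_d)
    raise SimConfigError(
        "progressor trajectory never reaches the diagnosis threshold within "
        "follow-up; check slope/rate ranges"
    )


def simulate_progressor(
    cfg: SimConfig, rng: np.random.Generator, patient_id: str = "P0"
) -> MeasurementSeries:
    """One progressor: sampled decline shape ending at the diagnosis date."""
    age0 = _draw_age(cfg, rng, cfg.entry_age_mean_progressor)
    shape, latent_fn, t_d = _sample_trajectory(cfg, rng)
    post_span = cfg.post_diagnosis_visits * cfg.visit_gap_mean_days / DAYS_PER_YEAR
    for _ in range(100):
        times = _visit_times(cfg, rng, t_d + post_span, min_visits=3)
        if int(np.sum(times < t_d)) >= 2:
            break
    else:
        raise SimConfigError("could not place >= 2 pre-diagnosis visits")
    latent = np.maximum(np.asarray(latent_fn(times), dtype=float), 5.0)
    series = _series_from_latent(
        cfg,
        rng,
        patient_id,
        group=1,
        age0=age0,
        times=times,
        latent=latent,
        floor=3.0,
        first_at_least=60.0,
    )
    series.diagnosis_date = series.dates[0] + timedelta(days=round(t_d * DAYS_PER_YEAR))
    series.flags["trajectory_shape"] = shape
    return series


# ------------------------------------------------------------------- decoys


def _decoy(cfg, rng, rule: str, patient_id: str) -> Tuple[RawPatient, str]:
    """A patient violating exactly one selection rule; returns expected reason."""
    sub = replace(cfg, decoys=False)
    if rule == "aki":
        # short record (<= 92 days), every eGFR below 90
        sex, race, flags = _demographics(cfg, rng, 0)
        entry = _entry_date(cfg, rng)
        age0 = _draw_age(cfg, rng, cfg.entry_age_mean_normal)
        birth = entry - timedelta(days=round(age0 * DAYS_PER_YEAR))
        dates = [entry + timedelta(days=int(d)) for d in (0, 15, 35, 60)]
        egfr = rng.uniform(40.0, 85.0, size=4)
        scr = [invert_ckd_epi(g, age0 + i / 12, sex) for i, g in enumerate(egfr)]
        raw = RawPatient(patient_id, sex, birth, list(zip(dates, scr)), [], flags, race)
        return raw, REASON_AKI
    if rule in ("egfr_below_60", "ckd_code", "too_few_measurements"):
        s = simulate_normal_patient(sub, rng, patient_id)
        obs = list(zip(s.dates, s.scr))
        codes = []
        if rule == "egfr_below_60":
            mid = len(obs) // 2
            d, _ = obs[mid]
            obs[mid] = (d, invert_ckd_epi(55.0, s.ages[mid], s.sex))
        elif rule == "ckd_code":
            codes = [("10", "N18.3", s.dates[len(s) // 2])]
        else:
            obs = obs[:8]
        raw = RawPatient(patient_id, s.sex, s.birth_date, obs, codes, s.flags, s.race)
        return raw, {
            "egfr_below_60": REASON_EGFR_BELOW_60,
            "ckd_code": REASON_CKD_CODE,
            "too_few_measurements": REASON_TOO_FEW,
        }[rule]
    if rule == "initial_egfr_below_60":
        s = simulate_progressor(sub, rng, patient_id)
        obs = list(zip(s.dates, s.scr))
        obs[0] = (s.dates[0], invert_ckd_epi(45.0, s.ages[0], s.sex))
        raw = RawPatient(
            patient_id, s.sex, s.birth_date, obs,
            [("10", "N18.6", s.diagnosis_date)], s.flags, s.race,
        )
        return raw, REASON_INITIAL_EGFR
    if rule == "no_pre_diagnosis_observations":
        s = simulate_progressor(sub, rng, patient_id)
        dx = s.dates[0] - timedelta(days=30)  # diagnosed before any observation
        raw = RawPatient(
            patient_id, s.sex, s.birth_date, list(zip(s.dates, s.scr)),
            [("10", "N18.6", dx)], s.flags, s.race,
        )
        return raw, REASON_NO_PRE_DX
    raise SimConfigError(f"unknown decoy rule {rule!r}")


DECOY_RULES = (
    "aki",
    "egfr_below_60",
    "ckd_code",
    "too_few_measurements",
    "initial_egfr_below_60",
    "no_pre_diagnosis_observations",
)


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Full labeled cohort plus the raw tables the cohort builder consumes."""
    rng = np.random.default_rng(cfg.seed)
    normal, eskd, raw, truth = [], [], [], []
    for i in range(cfg.n_normal):
        pid = f"N{i:05d}"
        s = simulate_normal_patient(cfg, rng, pid)
        normal.append(s)
        raw.append(
            RawPatient(pid, s.sex, s.birth_date, list(zip(s.dates, s.scr)), [], s.flags, s.race)
        )
        truth.append({"patient_id": pid, "role": "normal",
                      "expected_group": "normal", "expected_reason": ""})
    for i in range(cfg.n_progressor):
        pid = f"P{i:05d}"
        s = simulate_progressor(cfg, rng, pid)
        eskd.append(s)
        raw.append(
            RawPatient(
                pid, s.sex, s.birth_date, list(zip(s.dates, s.scr)),
                [("10", "N18.6", s.diagnosis_date)], s.flags, s.race,
            )
        )
        truth.append({"patient_id": pid, "role": "progressor",
                      "expected_group": "eskd", "expected_reason": ""})
    if cfg.decoys:
        for rule in DECOY_RULES:
            for j in range(cfg.n_decoys_per_rule):
                pid = f"D_{rule}_{j:02d}"
                raw_p, reason = _decoy(cfg, rng, rule, pid)
                raw.append(raw_p)
                truth.append({"patient_id": pid, "role": f"decoy_{rule}",
                              "expected_group": "excluded", "expected_reason": reason})
    return SimulatedCohort(
        cohort=LabeledCohort(normal=normal, eskd=eskd),
        raw_patients=raw,
        ground_truth=pd.DataFrame(truth),
    )
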