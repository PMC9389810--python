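"""Delimited-text readers/writers, configuration, and the end-to-end pipeline.

File schemas (CSV, ISO-8601 dates, creatinine in mg/dL):

* labs:          patient_id,date,scr_mg_dl
* demographics:  patient_id,sex,birth_date,race,hypertension,diabetes,
                 cardiovascular,hypercholesterolemia,smoking
* diagnoses:     patient_id,icd_version,code,date

eGFR is reported to two decimals in outputs; full precision is kept
internally.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from ._exceptions import InvalidInputError
from .cohort import (
    DEFAULT_CKD_EXCLUSION_CODES,
    DEFAULT_ESKD_CODES,
    build_cohort,
    estimate_reference,
    ks_normality_check,
)
from .cusum import CusumParams, NormalReference, run_cusum
from .evaluation import (
    DEFAULT_T_GRID,
    DEFAULT_W_GRID,
    classify_cohort,
    earliness_summary,
    kfold_tune,
    metrics,
)
from .series import LabeledCohort, MeasurementSeries, RawPatient
from .simulate import SimulatedCohort

logger = logging.getLogger("cusum_gfr")

LABS_COLUMNS = ("patient_id", "date", "scr_mg_dl")
DEMOGRAPHICS_COLUMNS = (
    "patient_id",
    "sex",
    "birth_date",
    "race",
    "hypertension",
    "diabetes",
    "cardiovascular",
    "hypercholesterolemia",
    "smoking",
)
DIAGNOSES_COLUMNS = ("patient_id", "icd_version", "code", "date")
FLAG_NAMES = ("hypertension", "diabetes", "cardiovascular", "hypercholesterolemia", "smoking")


# ------------------------------------------------------------------ writers


def write_cohort_tables(sim: SimulatedCohort, out_dir) -> Dict[str, Path]:
    """Write labs/demographics/diagnoses (+ ground truth) CSVs for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "labs": out / "labs.csv",
        "demographics": out / "demographics.csv",
        "diagnoses": out / "diagnoses.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    labs, demo, diag = [], [], []
    for p in sim.raw_patients:
        for d, scr in sorted(p.observations, key=lambda o: o[0]):
            labs.append({"patient_id": p.patient_id, "date": d.isoformat(),
                         "scr_mg_dl": f"{scr:.6f}"})
        row = {"patient_id": p.patient_id, "sex": p.sex,
               "birth_date": p.birth_date.isoformat(), "race": p.race or ""}
        for f in FLAG_NAMES:
            row[f] = int(bool(p.flags.get(f, False)))
        demo.append(row)
        for version, code, d in p.diagnosis_codes:
            diag.append({"patient_id": p.patient_id, "icd_version": version,
                         "code": code, "date": d.isoformat() if d else ""})
    pd.DataFrame(labs, columns=list(LABS_COLUMNS)).to_csv(paths["labs"], index=False)
    pd.DataFrame(demo, columns=list(DEMOGRAPHICS_COLUMNS)).to_csv(
        paths["demographics"], index=False
    )
    pd.DataFrame(diag, columns=list(DIAGNOSES_COLUMNS)).to_csv(
        paths["diagnoses"], index=False
    )
    sim.ground_truth.to_csv(paths["ground_truth"], index=False)
    return paths


def write_traces(
    cohort: LabeledCohort, ref: NormalReference, params: CusumParams, path
) -> None:
    """Per-observation trace export: patient, date, eGFR, CUSUM value, signal."""
    rows = []
    for s in list(cohort.normal) + list(cohort.eskd):
        trace = run_cusum(s, ref, params)
        for i, d in enumerate(s.dates):
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "date": d.isoformat(),
                    "egfr": round(float(s.egfr[i]), 2),
                    "cusum": round(float(trace.values[i]), 4),
                    "signaled": int(trace.signal_index is not None and i >= trace.signal_index),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ------------------------------------------------------------------ readers


def _parse_date(text: str) -> date:
    return date.fromisoformat(str(text).strip())


def read_labs(path) -> Tuple[Dict[str, List[Tuple[date, float]]], int]:
    """Lab events grouped per patient; malformed rows are logged and skipped.

    Returns (patient_id -> sorted [(date, scr)], number of skipped rows).
    """
    df = pd.read_csv(path, dtype=str)
    missing = set(LABS_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"labs file missing required columns: {sorted(missing)}")
    if df.empty:
        logger.warning("labs file %s contains no rows", path)
        return {}, 0
    obs: Dict[str, List[Tuple[date, float]]] = {}
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            d = _parse_date(row.date)
            scr = float(row.scr_mg_dl)
            if scr <= 0:
                raise ValueError("non-positive creatinine")
        except (ValueError, TypeError) as exc:
            skipped += 1
            logger.warning("skipping malformed lab row %r: %s", tuple(row), exc)
            continue
        obs.setdefault(str(row.patient_id), []).append((d, scr))
    for pid in obs:
        obs[pid].sort(key=lambda o: o[0])
    if skipped:
        logger.warning("skipped %d malformed lab rows", skipped)
    return obs, skipped


def read_raw_patients(labs_path, demographics_path, diagnoses_path=None) -> List[RawPatient]:
    """Join the three tables into RawPatient records (lab rows are required)."""
    obs, _ = read_labs(labs_path)
    demo = pd.read_csv(demographics_path, dtype=str).set_index("patient_id")
    codes: Dict[str, list] = {}
    if diagnoses_path is not None:
        diag = pd.read_csv(diagnoses_path, dtype=str)
        for row in diag.itertuples(index=False):
            d = _parse_date(row.date) if isinstance(row.date, str) and row.date.strip() else None
            codes.setdefault(str(row.patient_id), []).append(
                (str(row.icd_version), str(row.code), d)
            )
    patients = []
    for pid, observations in obs.items():
        if pid not in demo.index:
            raise InvalidInputError(f"patient {pid} has labs but no demographics row")
        row = demo.loc[pid]
        flags = {
            f: bool(int(float(row[f])))
            for f in FLAG_NAMES
            if f in demo.columns and pd.notna(row[f]) and str(row[f]).strip()
        }
        race_val = row["race"] if "race" in demo.columns else None
        race = str(race_val) if pd.notna(race_val) and str(race_val).strip() else None
        patients.append(
            RawPatient(
                patient_id=pid,
                sex=str(row["sex"]),
                birth_date=_parse_date(row["birth_date"]),
                observations=observations,
                diagnosis_codes=codes.get(pid, []),
                flags=flags,
                race=race,
            )
        )
    return patients


# ------------------------------------------------------------- configuration


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-loadable key/value text)."""

    labs: str = "labs.csv"
    demographics: str = "demographics.csv"
    diagnoses: Optional[str] = "diagnoses.csv"
    out_dir: str = "out"
    eskd_codes: Sequence[str] = DEFAULT_ESKD_CODES
    ckd_exclusion_codes: Sequence[str] = DEFAULT_CKD_EXCLUSION_CODES
    aki_window_days: int = 92
    min_normal_measurements: int = 9
    w_grid: Sequence[float] = DEFAULT_W_GRID
    T_grid: Sequence[float] = DEFAULT_T_GRID
    k: int = 10
    seed: int = 0
    refit_reference: bool = True

    def validate(self) -> "RunConfig":
        if not self.T_grid or not self.w_grid:
            raise InvalidInputError("w_grid and T_grid must be non-empty")
        if any(T > 0 for T in self.T_grid) or any(w < 0 for w in self.w_grid):
            raise InvalidInputError("need T <= 0 <= w throughout the grids")
        if self.k < 2:
            raise InvalidInputError("k must be >= 2")
        return self


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise InvalidInputError(f"unknown configuration keys: {sorted(unknown)}")
    return RunConfig(**raw).validate()


# ----------------------------------------------------------------- pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Selection → reference estimation → tuning → evaluation, with outputs.

    Deterministic under a fixed seed; writes the exclusion log, the (w, T)
    grid, per-patient signal records, ROC points and a plain-text report to
    ``config.out_dir`` and returns the report as a dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    patients = read_raw_patients(config.labs, config.demographics, config.diagnoses)
    cohort = build_cohort(
        patients,
        eskd_codes=config.eskd_codes,
        ckd_exclusion_codes=config.ckd_exclusion_codes,
        aki_window_days=config.aki_window_days,
        min_normal_measurements=config.min_normal_measurements,
    )
    pd.DataFrame(
        sorted(cohort.exclusion_log.items()), columns=["patient_id", "reason"]
    ).to_csv(out / "exclusion_log.csv", index=False)

    ref = estimate_reference(list(cohort.normal))
    all_normal_egfr = np.concatenate([s.egfr for s in cohort.normal])
    ks = ks_normality_check(all_normal_egfr)

    tuning = kfold_tune(
        cohort,
        w_grid=config.w_grid,
        T_grid=config.T_grid,
        k=config.k,
        seed=config.seed,
        refit_reference=config.refit_reference,
    )
    grid_rows = [
        {"w": w, "T": T, "sensitivity": m.sensitivity,
         "specificity": m.specificity, "accuracy": m.accuracy}
        for (w, T), m in sorted(tuning.grid.items())
    ]
    pd.DataFrame(grid_rows).to_csv(out / "grid.csv", index=False)
    pd.DataFrame(tuning.roc, columns=["fpr", "sensitivity"]).to_csv(
        out / "roc.csv", index=False
    )

    best_w, best_T = tuning.best
    params = CusumParams(w=best_w, T=best_T)
    records, counts = classify_cohort(cohort, ref, params)
    perf = metrics(counts)
    pd.DataFrame([vars(r) for r in records]).to_csv(out / "signals.csv", index=False)
    summary = earliness_summary(records)

    report = {
        "n_patients_in": len(patients),
        "n_normal": len(cohort.normal),
        "n_eskd": len(cohort.eskd),
        "n_excluded": len(cohort.exclusion_log),
        "reference_mean": ref.overall_mean,
        "reference_se": ref.overall_se,
        "reference_sigma": ref.sigma,
        "ks_statistic": ks.statistic,
        "ks_reject_normality": ks.reject,
        "best_w": best_w,
        "best_T": best_T,
        "cv_sensitivity": tuning.grid[tuning.best].sensitivity,
        "cv_specificity": tuning.grid[tuning.best].specificity,
        "cv_accuracy": tuning.grid[tuning.best].accuracy,
        "full_cohort_sensitivity": perf.sensitivity,
        "full_cohort_specificity": perf.specificity,
        "full_cohort_accuracy": perf.accuracy,
        "mean_earliness_days": summary.mean_days,
        "median_earliness_days": summary.median_days,
        "earliness_se_days": summary.se_days,
        "pct_signal_egfr_ge_30": 100 * summary.frac_egfr_ge_30,
        "pct_signal_egfr_ge_45": 100 * summary.frac_egfr_ge_45,
        "pct_signal_egfr_ge_60": 100 * summary.frac_egfr_ge_60,
    }
    lines = [f"{k}: {v}" for k, v in report.items()]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report


def config_to_yaml(config: RunConfig, path) -> None:
    data = asdict(config)
    data["eskd_codes"] = list(data["eskd_codes"])
    data["ckd_exclusion_codes"] = list(data["ckd_exclusion_codes"])
    data["w_grid"] = list(data["w_grid"])
    data["T_grid"] = list(data["T_grid"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
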