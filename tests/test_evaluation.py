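"""Cohort scoring, metric arithmetic, tuning, ROC, earliness and subgroups."""
from datetime import date

import numpy as np
import pytest

from cusum_gfr._exceptions import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedMetricError,
)
from cusum_gfr.cusum import CusumParams
from cusum_gfr.detector import CusumGfrDetector
from cusum_gfr.evaluation import (
    ConfusionCounts,
    SignalRecord,
    classify_cohort,
    earliness_summary,
    kfold_tune,
    metrics,
    roc_curve,
    subgroup_performance,
)
from cusum_gfr.series import LabeledCohort
from helpers import make_series


def tiny_cohort(flat_reference):
    """One flat normal series, one steep decliner diagnosed after its fall."""
    normal = make_series([85.0] * 6, patient_id="n1")
    decliner = make_series([85, 70, 55, 40, 30, 20], patient_id="e1", gap_days=120)
    decliner.diagnosis_date = decliner.dates[-1]
    return LabeledCohort(normal=[normal], eskd=[decliner])


class TestClassify:
    def test_hand_built_cohort(self, flat_reference):
        cohort = tiny_cohort(flat_reference)
        records, counts = classify_cohort(
            cohort, flat_reference, CusumParams(w=0.75, T=-4.0)
        )
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (1, 1, 0, 0)
        tp = [r for r in records if r.outcome == "tp"][0]
        assert tp.earliness_days > 0 and tp.pre_diagnosis

    def test_looser_threshold_never_more_specific(self, small_sim, flat_reference):
        _, sim = small_sim
        from cusum_gfr.cohort import estimate_reference

        ref = estimate_reference(list(sim.cohort.normal))
        _, strict = classify_cohort(sim.cohort, ref, CusumParams(w=0.75, T=-4.0))
        _, loose = classify_cohort(sim.cohort, ref, CusumParams(w=0.75, T=0.0))
        assert loose.tn <= strict.tn  # specificity at T=0 <= that at T=-4
        assert loose.tp >= strict.tp

    def test_empty_cohort_zero_counts(self, flat_reference):
        _, counts = classify_cohort(
            LabeledCohort(normal=[], eskd=[]), flat_reference, CusumParams()
        )
        assert counts.total == 0


class TestMetrics:
    def test_arithmetic(self):
        m = metrics(ConfusionCounts(tp=90, fn=10, tn=85, fp=15))
        assert m.sensitivity == pytest.approx(0.900)
        assert m.specificity == pytest.approx(0.850)
        assert m.accuracy == pytest.approx(0.875)

    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=5410, fn=0, tn=85699, fp=0))
        assert m.sensitivity == m.specificity == m.accuracy == 1.0

    def test_empty_class_is_an_error_not_zero(self):
        with pytest.raises(UndefinedMetricError):
            metrics(ConfusionCounts(tp=0, fn=0, tn=10, fp=0))


class TestKfoldTune:
    def test_separated_cohort_reaches_high_accuracy(self, small_sim):
        _, sim = small_sim
        res = kfold_tune(sim.cohort, k=5, seed=3)
        assert res.best in res.grid
        assert res.grid[res.best].accuracy >= 0.95

    def test_single_point_grid(self, small_sim):
        _, sim = small_sim
        res = kfold_tune(sim.cohort, w_grid=[0.75], T_grid=[-4.0], k=5, seed=3)
        assert res.best == (0.75, -4.0)

    def test_deterministic_under_seed(self, small_sim):
        _, sim = small_sim
        r1 = kfold_tune(sim.cohort, k=5, seed=11)
        r2 = kfold_tune(sim.cohort, k=5, seed=11)
        assert r1.best == r2.best
        for key in r1.grid:
            assert r1.grid[key] == r2.grid[key]
        assert r1.roc == r2.roc

    def test_empty_grid_rejected(self, small_sim):
        _, sim = small_sim
        with pytest.raises(InvalidInputError):
            kfold_tune(sim.cohort, w_grid=[], T_grid=[-4.0])

    def test_converges_to_full_cohort_metrics_at_large_k(self, small_sim):
        _, sim = small_sim
        from cusum_gfr.cohort import estimate_reference

        ref = estimate_reference(list(sim.cohort.normal))
        res = kfold_tune(
            sim.cohort, w_grid=[0.75], T_grid=[-4.0], k=20, seed=1,
            refit_reference=False, reference=ref,
        )
        _, counts = classify_cohort(sim.cohort, ref, CusumParams(0.75, -4.0))
        full = metrics(counts)
        cv = res.grid[(0.75, -4.0)]
        assert cv.accuracy == pytest.approx(full.accuracy, abs=0.05)


class TestRoc:
    def test_monotone_and_near_perfect_on_separated_cohort(self, small_sim):
        _, sim = small_sim
        from cusum_gfr.cohort import estimate_reference

        ref = estimate_reference(list(sim.cohort.normal))
        res = roc_curve(sim.cohort, ref, w=0.75, T_grid=[-6, -5, -4, -3, -2, -1])
        sens = [p[1] for p in res.points]
        fpr = [p[0] for p in res.points]
        assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(fpr, fpr[1:]))
        assert 0.95 <= res.auc <= 1.0

    def test_random_labels_give_chance_auc(self):
        rng = np.random.default_rng(5)
        from cusum_gfr.cusum import NormalReference

        ref = NormalReference(
            mu0_by_age={a: 85.0 for a in range(18, 100)}, sigma=7.8,
            decline_rate=0.0, overall_mean=85.0,
        )
        series = [
            make_series(rng.normal(85, 7.8, size=12), patient_id=f"s{i}")
            for i in range(200)
        ]
        labels = rng.permutation([0] * 100 + [1] * 100)
        normal = [s for s, l in zip(series, labels) if l == 0]
        eskd = []
        for s in (s for s, l in zip(series, labels) if l == 1):
            s.diagnosis_date = date(2030, 1, 1)
            eskd.append(s)
        cohort = LabeledCohort(normal=normal, eskd=eskd)
        res = roc_curve(cohort, ref, w=0.5, T_grid=list(np.linspace(-8, 0, 17)))
        assert res.auc == pytest.approx(0.5, abs=0.12)

    def test_degenerate_single_threshold(self, small_sim):
        _, sim = small_sim
        from cusum_gfr.cohort import estimate_reference

        ref = estimate_reference(list(sim.cohort.normal))
        res = roc_curve(sim.cohort, ref, w=0.75, T_grid=[-4.0])
        assert len(res.points) == 1 and res.auc is None

    def test_auc_invariant_to_duplicate_thresholds(self, small_sim):
        _, sim = small_sim
        from cusum_gfr.cohort import estimate_reference

        ref = estimate_reference(list(sim.cohort.normal))
        a = roc_curve(sim.cohort, ref, w=0.75, T_grid=[-6, -4, -2]).auc
        b = roc_curve(sim.cohort, ref, w=0.75, T_grid=[-6, -4, -4, -2]).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestEarlinessSummary:
    def _tp(self, pid, days, egfr):
        return SignalRecord(pid, "eskd", True, earliness_days=days,
                            egfr_at_signal=egfr, pre_diagnosis=days > 0, outcome="tp")

    def test_arithmetic(self):
        recs = [self._tp("a", 100, 65.0), self._tp("b", 200, 50.0),
                self._tp("c", 300, 25.0)]
        s = earliness_summary(recs)
        assert s.mean_days == 200 and s.median_days == 200
        assert s.frac_egfr_ge_30 == pytest.approx(2 / 3)
        assert s.frac_egfr_ge_45 == pytest.approx(2 / 3)
        assert s.frac_egfr_ge_60 == pytest.approx(1 / 3)

    def test_post_diagnosis_signals_do_not_qualify(self):
        recs = [self._tp("a", -30, 20.0)]
        with pytest.raises(InsufficientDataError):
            earliness_summary(recs)


class TestSubgroups:
    def test_builtin_effect_shows_in_flagged_level(self, flat_reference):
        # flagged progressors are given longer pre-diagnosis records
        normal = [make_series([85.0] * 9, patient_id=f"n{i}") for i in range(6)]
        eskd = []
        for i in range(8):
            long_record = i < 4
            n = 14 if long_record else 5
            vals = list(np.linspace(85, 25, n))
            s = make_series(vals, patient_id=f"e{i}", gap_days=120)
            s.diagnosis_date = s.dates[-1]
            s.flags["diabetes"] = long_record
            eskd.append(s)
        cohort = LabeledCohort(normal=normal, eskd=eskd)
        records, _ = classify_cohort(cohort, flat_reference, CusumParams(0.75, -4.0))
        table = subgroup_performance(cohort, records, "diabetes")
        assert (
            table.loc[True, "mean_earliness_days"]
            > table.loc[False, "mean_earliness_days"]
        )

    def test_single_level_matches_overall(self):
        from cusum_gfr.cohort import estimate_reference
        from cusum_gfr.simulate import SimConfig, simulate_cohort

        sim = simulate_cohort(SimConfig(n_normal=40, n_progressor=12, seed=9))
        ref = estimate_reference(list(sim.cohort.normal))
        records, counts = classify_cohort(sim.cohort, ref, CusumParams(0.75, -4.0))
        overall = metrics(counts)
        for s in list(sim.cohort.normal) + list(sim.cohort.eskd):
            s.flags["hypertension"] = True
        table = subgroup_performance(sim.cohort, records, "hypertension")
        assert len(table) == 1
        assert table.iloc[0]["accuracy"] == pytest.approx(overall.accuracy)

    def test_level_without_eskd_flagged_undefined(self, flat_reference):
        normal = [make_series([85.0] * 9, patient_id=f"n{i}", sex="female")
                  for i in range(3)]
        eskd_series = make_series(list(np.linspace(85, 25, 8)), patient_id="e0",
                                  gap_days=120, sex="male")
        eskd_series.diagnosis_date = eskd_series.dates[-1]
        cohort = LabeledCohort(normal=normal, eskd=[eskd_series])
        records, _ = classify_cohort(cohort, flat_reference, CusumParams(0.75, -4.0))
        table = subgroup_performance(cohort, records, "sex")
        assert not table.loc["female", "defined"]
        assert np.isnan(table.loc["female", "sensitivity"])

    def test_unknown_stratifier_rejected(self, small_sim, flat_reference):
        _, sim = small_sim
        with pytest.raises(InvalidInputError):
            subgroup_performance(sim.cohort, [], "shoe_size")


class TestDetectorEstimator:
    def test_sklearn_contract(self, small_sim):
        _, sim = small_sim
        X = np.array(list(sim.cohort.normal) + list(sim.cohort.eskd), dtype=object)
        y = np.array([0] * len(sim.cohort.normal) + [1] * len(sim.cohort.eskd))
        det = CusumGfrDetector(w=0.75, T=-4.0)
        assert det.get_params()["w"] == 0.75
        det.set_params(w=1.0).fit(X, y)
        preds = det.predict(X)
        assert set(preds) <= {0, 1}
        assert det.score(X, y) >= 0.9
        scores = det.decision_function(X)
        assert np.all((preds == 1) == (scores >= -det.T))

    def test_cross_val_score_integration(self, small_sim):
        from sklearn.model_selection import StratifiedKFold, cross_val_score

        _, sim = small_sim
        X = np.array(list(sim.cohort.normal) + list(sim.cohort.eskd), dtype=object)
        y = np.array([0] * len(sim.cohort.normal) + [1] * len(sim.cohort.eskd))
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        scores = cross_val_score(CusumGfrDetector(), X, y, cv=cv)
        assert scores.mean() >= 0.9
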