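"""Metrics arithmetic, statistical comparisons and workflow mechanics."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from xfall import evaluation as ev
from xfall import synthetic_data as sd


class TestMetrics:
    def test_sensitivity_fourteen_of_fifteen(self):
        m = ev.compute_metrics(ev.ConfusionCounts(tp=14, fn=1, tn=0, fp=0))
        assert m.sensitivity == pytest.approx(14 / 15)
        assert m.specificity is None  # no negatives present

    def test_perfect_classifier(self):
        m = ev.compute_metrics(ev.ConfusionCounts(tp=5, tn=5))
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_symmetric_counts_give_one_half(self):
        m = ev.compute_metrics(ev.ConfusionCounts(25, 25, 25, 25))
        assert (m.accuracy, m.sensitivity, m.specificity) == (0.5, 0.5, 0.5)

    def test_hundred_random_tables_match_exact_arithmetic(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 60, size=4))
            if tp + tn + fp + fn == 0:
                continue
            m = ev.compute_metrics(ev.ConfusionCounts(tp, tn, fp, fn))
            assert m.accuracy == pytest.approx(
                float(Fraction(tp + tn, tp + tn + fp + fn)), abs=0
            )
            if tp + fn:
                assert m.sensitivity == pytest.approx(float(Fraction(tp, tp + fn)), abs=0)
            else:
                assert m.sensitivity is None
            if tn + fp:
                assert m.specificity == pytest.approx(float(Fraction(tn, tn + fp)), abs=0)
            else:
                assert m.specificity is None

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.compute_metrics(ev.ConfusionCounts())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.ConfusionCounts(tp=-1)

    def test_confusion_from_labels(self):
        y_true = ["FALL", "FALL", "ADL", "ADL", "ADL"]
        y_pred = ["FALL", "ADL", "ADL", "FALL", "ADL"]
        c = ev.ConfusionCounts.from_labels(y_true, y_pred)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 2)


class TestSplitSubjects:
    def test_default_split_is_six_of_twentythree(self):
        subjects = [f"SA{i:02d}" for i in range(1, 24)]
        rng = np.random.default_rng(0)
        train, test = ev.split_subjects(subjects, 6, rng)
        assert len(test) == 6 and len(train) == 17
        assert not set(train) & set(test)
        assert sorted(train + test) == sorted(subjects)

    def test_degenerate_sizes_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            ev.split_subjects(["a", "b"], 2, rng)
        with pytest.raises(ValueError):
            ev.split_subjects(["a", "b", "c"], 0, rng)


def _fake_runs(groups: dict, eval_set="cross_domain", metric="accuracy") -> pd.DataFrame:
    rows = []
    for family, values in groups.items():
        for i, v in enumerate(values):
            rows.append(
                {"classifier": family, "trial": 1, "repetition": i,
                 "eval_set": eval_set, metric: v}
            )
    return pd.DataFrame(rows)


class TestCompareClassifiers:
    def test_identical_distributions_are_not_significant(self):
        runs = _fake_runs({f: [0.9, 0.91, 0.92, 0.9] * 5 for f in ("SVM", "KNN", "RF")})
        res = ev.compare_classifiers(runs)
        assert res.undefined or res.pvalue > 0.05
        assert res.posthoc is None

    def test_constant_identical_samples_reported_undefined(self):
        runs = _fake_runs({f: [0.9] * 5 for f in ("SVM", "KNN")})
        res = ev.compare_classifiers(runs)
        assert res.undefined
        assert res.pvalue is None

    def test_planted_dominant_classifier_wins_posthoc(self):
        rng = np.random.default_rng(1)
        runs = _fake_runs(
            {
                "SVM": 0.95 + 0.01 * rng.normal(size=50),
                "KNN": 0.80 + 0.01 * rng.normal(size=50),
                "RF": 0.80 + 0.01 * rng.normal(size=50),
            }
        )
        res = ev.compare_classifiers(runs)
        assert res.pvalue < 0.05
        assert res.posthoc is not None
        svm_rows = res.posthoc[
            (res.posthoc["a"] == "SVM") | (res.posthoc["b"] == "SVM")
        ]
        assert len(svm_rows) == 2
        assert all(svm_rows["significant"])
        assert all(svm_rows["better"] == "SVM")

    def test_two_families_use_unadjusted_alpha(self):
        rng = np.random.default_rng(2)
        runs = _fake_runs(
            {"SVM": 0.95 + 0.01 * rng.normal(size=30),
             "KNN": 0.70 + 0.01 * rng.normal(size=30)}
        )
        res = ev.compare_classifiers(runs, alpha=0.05)
        assert res.posthoc["alpha_adjusted"].iloc[0] == 0.05  # one pair only

    def test_single_family_rejected(self):
        runs = _fake_runs({"SVM": [0.9, 0.8]})
        with pytest.raises(ValueError):
            ev.compare_classifiers(runs)


class TestGeneralizationGap:
    def test_detects_planted_drop(self):
        rng = np.random.default_rng(3)
        runs = pd.concat(
            [
                _fake_runs({"SVM": 0.97 + 0.01 * rng.normal(size=20)}, "in_domain"),
                _fake_runs({"SVM": 0.80 + 0.01 * rng.normal(size=20)}, "cross_domain"),
            ]
        )
        gap = ev.generalization_gap(runs, "SVM")
        assert gap.drop == pytest.approx(0.17, abs=0.02)
        assert gap.significant()

    def test_no_gap_when_distributions_match(self):
        runs = pd.concat(
            [
                _fake_runs({"SVM": [0.9, 0.91, 0.9, 0.92] * 3}, "in_domain"),
                _fake_runs({"SVM": [0.9, 0.91, 0.9, 0.92] * 3}, "cross_domain"),
            ]
        )
        gap = ev.generalization_gap(runs, "SVM")
        assert not gap.significant()


@pytest.fixture(scope="module")
def tiny_workflow_report(tiny_catalog):
    """A minimal but complete run: 6 subjects, 1 trial, 2 repetitions, SVM."""
    lab = sd.generate_lab_cohort(
        sd.CohortSpec(n_subjects=6, n_trials_per_activity=1, seed=21), tiny_catalog
    )
    rw = sd.generate_realworld_set(5, sd.DomainShift.default(), seed=22, catalog=tiny_catalog)
    cfg = ev.ExperimentConfig(
        n_test_subjects=2, n_repetitions=2, n_trials=1, families=("SVM",),
        sbs_folds=2, grid_folds=2, seed=5, keep_models=True,
    )
    return ev.run_workflow(lab, rw, cfg), cfg


class TestRunWorkflow:
    def test_row_count_formula(self, tiny_workflow_report):
        report, cfg = tiny_workflow_report
        expected = cfg.n_repetitions * cfg.n_trials * len(cfg.families)
        assert len(report.runs) == expected * 2  # in-domain + cross-domain rows
        per_family = report.runs.groupby("classifier").size()
        assert (per_family == expected * 2).all()

    def test_no_subject_leakage_in_any_run(self, tiny_workflow_report):
        report, _ = tiny_workflow_report
        for _, row in report.runs.iterrows():
            train = set(row["train_subjects"].split("|"))
            test = set(row["test_subjects"].split("|"))
            assert not train & test

    def test_models_carry_frozen_training_standardization(self, tiny_workflow_report):
        report, _ = tiny_workflow_report
        assert report.models
        for model, prov in zip(report.models, report.provenance):
            mean, sdv = model.standardization
            assert np.array_equal(mean, prov["mean"])
            assert np.array_equal(sdv, prov["sd"])
            assert model.provenance["standardization_source"] == "lab-train"

    def test_cross_domain_evaluation_is_deterministic_and_frozen(
        self, tiny_workflow_report, tiny_catalog
    ):
        report, _ = tiny_workflow_report
        rw = sd.generate_realworld_set(5, sd.DomainShift.default(), seed=22,
                                       catalog=tiny_catalog)
        cfg = report.config
        rw_fm = ev.prepare_realworld_features(rw, cfg)
        model = report.models[0]
        before = model.standardization[0].copy()
        first = model.predict(rw_fm.X)
        second = model.predict(rw_fm.X)
        assert np.array_equal(first, second)
        assert np.array_equal(model.standardization[0], before)

    def test_too_few_subjects_rejected(self, tiny_catalog):
        lab = sd.generate_lab_cohort(
            sd.CohortSpec(n_subjects=3, n_trials_per_activity=1, seed=0), tiny_catalog
        )
        rw = sd.generate_realworld_set(2, seed=1, catalog=tiny_catalog)
        with pytest.raises(ValueError):
            ev.run_workflow(lab, rw, ev.ExperimentConfig(n_test_subjects=2, n_trials=1))

    def test_report_written_to_disk(self, tiny_workflow_report, tmp_path):
        report, _ = tiny_workflow_report
        out = ev.write_report(report, tmp_path / "report")
        assert (out / "runs.csv").exists()
        assert (out / "summary.csv").exists()
        assert (out / "stats.json").exists()


class TestNoShiftControl:
    def test_identity_shift_gives_agreeing_in_and_cross_domain_accuracy(self):
        """Without a domain shift the pipeline must not fabricate a
        generalization gap: in-domain and cross-domain accuracies agree
        within 3 SD of the repetition spread (floored at one-segment
        resolution)."""
        lab = sd.generate_lab_cohort(sd.CohortSpec(n_subjects=6, n_trials_per_activity=1, seed=51))
        rw = sd.generate_realworld_set(10, sd.DomainShift.identity(200.0), seed=52)
        cfg = ev.ExperimentConfig(
            n_test_subjects=2, n_repetitions=2, n_trials=1, families=("SVM",),
            sbs_folds=2, grid_folds=2, seed=3,
        )
        report = ev.run_workflow(lab, rw, cfg)
        gap = ev.generalization_gap(report, "SVM")
        in_sd = report.runs.loc[
            report.runs["eval_set"] == "in_domain", "accuracy"
        ].std()
        tolerance = max(3 * (0.0 if np.isnan(in_sd) else in_sd), 0.05)
        assert abs(gap.drop) <= tolerance


class TestWindowLengthSweep:
    def test_per_length_reports_share_schema_and_are_reproducible(self, tiny_catalog):
        lab = sd.generate_lab_cohort(
            sd.CohortSpec(n_subjects=5, n_trials_per_activity=1, seed=31), tiny_catalog
        )
        rw = sd.generate_realworld_set(3, seed=32, catalog=tiny_catalog)
        cfg = ev.ExperimentConfig(
            n_test_subjects=2, n_repetitions=1, n_trials=1, families=("SVM",),
            sbs_folds=2, grid_folds=2, seed=9,
        )
        sweep = ev.window_length_sweep(lab, rw, lengths=(250, 500), config=cfg)
        assert set(sweep) == {250, 500}
        cols = list(sweep[250].runs.columns)
        assert cols == list(sweep[500].runs.columns)
        again = ev.window_length_sweep(lab, rw, lengths=(250,), config=cfg)
        pd.testing.assert_frame_equal(sweep[250].runs, again[250].runs)

    def test_window_length_in_seconds(self):
        # 500 samples at 200 Hz = 2.5 s epochs; 250 = 1.25 s
        assert 500 / 200.0 == 2.5
        assert 250 / 200.0 == 1.25
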