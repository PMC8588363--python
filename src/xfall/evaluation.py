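"""Repeated subject-wise training/testing and cross-dataset validation.

The workflow trains on one domain (lab-style scripted trials) and measures
generalization to the other (real-world-style continuous traces):

1. hold out ``n_test_subjects`` randomly chosen subjects;
2. on the remaining subjects' data of one trial index: sequential backward
   feature selection, then grid search, then a final fit — all inside the
   training set only;
3. evaluate the frozen model (training standardization, selected features,
   tuned hyperparameters) on the held-out lab subjects AND on the whole
   real-world set;
4. repeat ``n_repetitions`` times per trial index, for every trial index.

Performance is summarized by accuracy, sensitivity and specificity from the
fall/ADL confusion counts, classifiers are compared with a Kruskal-Wallis
test followed by Bonferroni-corrected Mann-Whitney-U post hoc tests, and a
per-family in-domain vs cross-domain comparison quantifies the
generalization gap. A 3 g magnitude-threshold oracle provides a
separability lower bound on the synthetic data.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import model_selection as ms
from .features import FeatureMatrix, feature_matrix, standardize
from .segmentation import (
    SampEnParams,
    calibrate_threshold,
    epoch,
    extract_fall_segment,
    label_realworld,
)
from .signal_io import LABEL_ADL, LABEL_FALL, TraceDataset, resample_trace

__all__ = [
    "ConfusionCounts",
    "PerformanceMetrics",
    "ExperimentConfig",
    "RepetitionReport",
    "ComparisonResult",
    "GapResult",
    "compute_metrics",
    "split_subjects",
    "prepare_lab_features",
    "prepare_realworld_features",
    "oracle_predict",
    "run_workflow",
    "compare_classifiers",
    "generalization_gap",
    "window_length_sweep",
    "write_report",
]

METRICS = ("accuracy", "sensitivity", "specificity")


@dataclass
class ConfusionCounts:
    """Fall-detection confusion counts; a true positive is a detected fall."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )

    @classmethod
    def from_labels(cls, y_true, y_pred, positive: str = LABEL_FALL) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


@dataclass
class PerformanceMetrics:
    """Accuracy, sensitivity (fall detection rate) and specificity
    (ADL rejection rate); ``None`` marks an undefined metric."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def compute_metrics(counts: ConfusionCounts) -> PerformanceMetrics:
    """accuracy = (TP+TN)/(TP+TN+FP+FN); specificity = TN/(TN+FP);
    sensitivity = TP/(TP+FN); zero denominators yield ``None``."""
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    acc = (counts.tp + counts.tn) / counts.total
    sens = counts.tp / (counts.tp + counts.fn) if (counts.tp + counts.fn) > 0 else None
    spec = counts.tn / (counts.tn + counts.fp) if (counts.tn + counts.fp) > 0 else None
    return PerformanceMetrics(accuracy=acc, sensitivity=sens, specificity=spec)


@dataclass
class ExperimentConfig:
    """Knobs of the repeated subject-wise cross-dataset experiment."""

    n_test_subjects: int = 6
    n_repetitions: int = 10
    n_trials: int = 5
    window_samples: int = 500
    overlap: float = 0.0
    seed: int = 0
    families: tuple[str, ...] = ("SVM", "KNN", "RF")
    target_rate: float = 200.0
    sampen: SampEnParams = field(default_factory=SampEnParams)
    magnitude_mode: str = "l1"
    sbs_folds: int = 5
    sbs_tolerance: float = 0.0
    grid_folds: int = 5
    grid: ms.HyperparamGrid | None = None
    min_features: int = 1
    oracle_threshold_g: float = 3.0
    keep_models: bool = False


@dataclass
class ComparisonResult:
    """Kruskal-Wallis across classifier families plus post hoc tests."""

    metric: str
    eval_set: str
    statistic: float | None
    pvalue: float | None
    undefined: bool
    posthoc: pd.DataFrame | None
    group_means: dict

    @property
    def significant(self) -> bool:
        return bool(self.pvalue is not None and self.pvalue < 0.05)


@dataclass
class GapResult:
    """In-domain vs cross-domain comparison for one classifier family."""

    family: str
    metric: str
    in_mean: float
    cross_mean: float
    statistic: float | None
    pvalue: float | None

    @property
    def drop(self) -> float:
        return self.in_mean - self.cross_mean

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(self.pvalue is not None and self.pvalue < alpha and self.drop > 0)


@dataclass
class RepetitionReport:
    """Per-run confusion counts/metrics and aggregate summaries."""

    runs: pd.DataFrame
    summary: pd.DataFrame
    config: ExperimentConfig
    sampen_threshold: float
    provenance: list = field(default_factory=list)
    models: list = field(default_factory=list)


def split_subjects(subjects, n_test: int, rng: np.random.Generator):
    """Random disjoint train/test subject partition (test size ``n_test``)."""
    subjects = sorted(set(subjects))
    if not 0 < n_test < len(subjects):
        raise ValueError("n_test_subjects must lie strictly between 0 and cohort size")
    test = sorted(rng.choice(subjects, size=n_test, replace=False).tolist())
    train = sorted(s for s in subjects if s not in test)
    return tuple(train), tuple(test)


def prepare_lab_features(
    lab: TraceDataset, config: ExperimentConfig
) -> tuple[FeatureMatrix, float]:
    """Segment, align and featurize a lab dataset.

    ADL trials are epoched wholesale; each fall trial contributes only its
    SampEn-aligned impact window. Returns the feature matrix and the
    calibrated SampEn threshold.
    """
    falls = lab.fall_traces()
    adls = lab.adl_traces()
    if not falls or not adls:
        raise ValueError("lab dataset needs both fall and ADL trials")
    threshold = calibrate_threshold(
        falls, adls, config.window_samples, config.sampen, config.overlap
    )
    segments = []
    for trace in adls:
        segments.extend(epoch(trace, config.window_samples, config.overlap))
    for trace in falls:
        seg, _ = extract_fall_segment(
            trace, config.window_samples, config.sampen, threshold, config.overlap
        )
        segments.append(seg)
    return feature_matrix(segments, config.magnitude_mode), threshold


def prepare_realworld_features(
    realworld: TraceDataset, config: ExperimentConfig
) -> FeatureMatrix:
    """Resample real-world traces to the common rate and apply the fixed
    labeling convention around the known impact time."""
    segments = []
    for trace in realworld:
        if not math.isclose(trace.rate, config.target_rate):
            trace = resample_trace(trace, config.target_rate)
        window_seconds = config.window_samples / config.target_rate
        segments.extend(label_realworld(trace, window_seconds=window_seconds))
    return feature_matrix(segments, config.magnitude_mode)


def oracle_predict(fm: FeatureMatrix, threshold_g: float = 3.0) -> np.ndarray:
    """Magnitude-threshold oracle: FALL iff the segment's peak Euclidean
    magnitude exceeds ``threshold_g`` — a separability lower bound."""
    if fm.peak_magnitude is None:
        raise ValueError("feature matrix lacks peak magnitudes")
    return np.where(fm.peak_magnitude > threshold_g, LABEL_FALL, LABEL_ADL)


def _metric_row(counts: ConfusionCounts) -> dict:
    m = compute_metrics(counts)
    return {
        "tp": counts.tp,
        "tn": counts.tn,
        "fp": counts.fp,
        "fn": counts.fn,
        **{k: (np.nan if v is None else v) for k, v in m.as_dict().items()},
    }


def run_workflow(
    lab: TraceDataset,
    realworld: TraceDataset,
    config: ExperimentConfig | None = None,
) -> RepetitionReport:
    """Execute the full repeated subject-wise cross-dataset experiment."""
    config = config or ExperimentConfig()
    subjects = lab.subjects()
    if len(subjects) < config.n_test_subjects + 2:
        raise ValueError(
            f"need at least {config.n_test_subjects + 2} subjects, got {len(subjects)}"
        )
    grid = config.grid or ms.HyperparamGrid.default()

    lab_fm, threshold = prepare_lab_features(lab, config)
    rw_fm = prepare_realworld_features(realworld, config)
    if config.n_trials > int(np.max(lab_fm.trials)):
        raise ValueError("config.n_trials exceeds trials present in the lab data")

    rows = []
    provenance = []
    models = []
    for trial in range(1, config.n_trials + 1):
        trial_mask = lab_fm.trials == trial
        trial_fm = lab_fm.subset(trial_mask)
        for rep in range(1, config.n_repetitions + 1):
            child = np.random.SeedSequence([config.seed, trial, rep])
            rng = np.random.default_rng(child)
            model_seed = int(rng.integers(2**31))
            train_subj, test_subj = split_subjects(
                subjects, config.n_test_subjects, rng
            )
            assert not set(train_subj) & set(test_subj)
            train_fm = trial_fm.subset(np.isin(trial_fm.subject_ids, train_subj))
            test_fm = trial_fm.subset(np.isin(trial_fm.subject_ids, test_subj))
            train_std, (test_std, rw_std), mean, sd = standardize(
                train_fm, [test_fm, rw_fm]
            )
            oracle_in = ConfusionCounts.from_labels(
                test_fm.labels, oracle_predict(test_fm, config.oracle_threshold_g)
            )
            oracle_cross = ConfusionCounts.from_labels(
                rw_fm.labels, oracle_predict(rw_fm, config.oracle_threshold_g)
            )
            for family in config.families:
                selected = ms.sequential_backward_selection(
                    train_std.X,
                    train_std.labels,
                    ms.ClassifierSpec.default(family),
                    groups=train_std.subject_ids,
                    folds=config.sbs_folds,
                    tolerance=config.sbs_tolerance,
                    seed=model_seed,
                    min_features=config.min_features,
                )
                best_spec = ms.grid_search(
                    family,
                    grid,
                    train_std.X[:, selected],
                    train_std.labels,
                    groups=train_std.subject_ids,
                    folds=config.grid_folds,
                    seed=model_seed,
                )
                model = ms.fit(
                    best_spec,
                    train_std.X,
                    train_std.labels,
                    seed=model_seed,
                    selected_features=selected,
                    standardization=(mean, sd),
                    provenance={
                        "trial": trial,
                        "repetition": rep,
                        "train_subjects": train_subj,
                        "test_subjects": test_subj,
                        "seed": model_seed,
                        "standardization_source": "lab-train",
                    },
                )
                for eval_set, fm_raw in (
                    ("in_domain", test_fm),
                    ("cross_domain", rw_fm),
                ):
                    counts = ConfusionCounts.from_labels(
                        fm_raw.labels, model.predict(fm_raw.X)
                    )
                    oracle = oracle_in if eval_set == "in_domain" else oracle_cross
                    rows.append(
                        {
                            "classifier": family,
                            "trial": trial,
                            "repetition": rep,
                            "eval_set": eval_set,
                            **_metric_row(counts),
                            "oracle_accuracy": compute_metrics(oracle).accuracy,
                            "n_selected_features": int(selected.size),
                            "hyperparams": json.dumps(best_spec.hyperparams),
                            "train_subjects": "|".join(train_subj),
                            "test_subjects": "|".join(test_subj),
                            "model_seed": model_seed,
                        }
                    )
                provenance.append(
                    {
                        "trial": trial,
                        "repetition": rep,
                        "family": family,
                        "mean": mean.copy(),
                        "sd": sd.copy(),
                        "selected_features": selected.copy(),
                        "hyperparams": dict(best_spec.hyperparams),
                        "train_subjects": train_subj,
                        "test_subjects": test_subj,
                    }
                )
                if config.keep_models:
                    models.append(model)

    runs = pd.DataFrame(rows)
    summary = (
        runs.groupby(["classifier", "eval_set"])[list(METRICS)]
        .agg(["mean", "std"])
        .reset_index()
    )
    return RepetitionReport(
        runs=runs,
        summary=summary,
        config=config,
        sampen_threshold=threshold,
        provenance=provenance,
        models=models,
    )


def _per_run_values(report, metric: str, eval_set: str) -> pd.DataFrame:
    runs = report.runs if isinstance(report, RepetitionReport) else report
    df = runs[runs["eval_set"] == eval_set][["classifier", metric]].dropna()
    return df


def compare_classifiers(
    report,
    metric: str = "accuracy",
    eval_set: str = "cross_domain",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Kruskal-Wallis across classifier families on the per-run metric;
    when significant, all pairwise Mann-Whitney-U tests at the
    Bonferroni-adjusted level ``alpha / n_pairs``.

    Identical constant samples make the rank tests undefined; that case is
    reported as such rather than raising.
    """
    df = _per_run_values(report, metric, eval_set)
    families = sorted(df["classifier"].unique())
    if len(families) < 2:
        raise ValueError("need at least two classifier families to compare")
    groups = [df.loc[df["classifier"] == f, metric].to_numpy() for f in families]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least two runs per classifier")
    means = {f: float(np.mean(g)) for f, g in zip(families, groups)}
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return ComparisonResult(metric, eval_set, None, None, True, None, means)
    stat, p = sps.kruskal(*groups)
    posthoc = None
    if p < alpha:
        pairs = list(itertools.combinations(range(len(families)), 2))
        adj_alpha = alpha / len(pairs)
        rows = []
        for i, j in pairs:
            a, b = groups[i], groups[j]
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                u, pu = np.nan, np.nan
            else:
                u, pu = sps.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {
                    "a": families[i],
                    "b": families[j],
                    "U": u,
                    "p_raw": pu,
                    "alpha_adjusted": adj_alpha,
                    "significant": bool(pu < adj_alpha) if not np.isnan(pu) else False,
                    "better": families[i]
                    if np.median(a) > np.median(b)
                    else families[j],
                }
            )
        posthoc = pd.DataFrame(rows)
    return ComparisonResult(metric, eval_set, float(stat), float(p), False, posthoc, means)


def generalization_gap(
    report, family: str, metric: str = "accuracy", alpha: float = 0.05
) -> GapResult:
    """Compare one family's in-domain vs cross-domain per-run metric
    (Kruskal-Wallis on the two groups)."""
    runs = report.runs if isinstance(report, RepetitionReport) else report
    sub = runs[runs["classifier"] == family]
    a = sub.loc[sub["eval_set"] == "in_domain", metric].dropna().to_numpy()
    b = sub.loc[sub["eval_set"] == "cross_domain", metric].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two runs per evaluation set")
    if np.all(np.concatenate([a, b]) == a[0]):
        return GapResult(family, metric, float(a.mean()), float(b.mean()), None, None)
    stat, p = sps.kruskal(a, b)
    return GapResult(family, metric, float(a.mean()), float(b.mean()), float(stat), float(p))


def window_length_sweep(
    lab: TraceDataset,
    realworld: TraceDataset,
    lengths=(250, 500, 750),
    config: ExperimentConfig | None = None,
) -> dict[int, RepetitionReport]:
    """Re-run the workflow per window length for the SVM family.

    Each report has identical schema; seed-reproducible given the config
    seed.
    """
    config = config or ExperimentConfig()
    out = {}
    for length in lengths:
        if length < 2:
            raise ValueError("window lengths must be at least 2 samples")
        cfg = replace(config, window_samples=int(length), families=("SVM",))
        out[int(length)] = run_workflow(lab, realworld, cfg)
    return out


def write_report(report: RepetitionReport, out_dir) -> Path:
    """Write ``runs.csv``, ``summary.csv`` and ``stats.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.runs.to_csv(out_dir / "runs.csv", index=False)
    summary = report.summary.copy()
    summary.columns = [
        "_".join(c) if isinstance(c, tuple) and c[1] else (c[0] if isinstance(c, tuple) else c)
        for c in summary.columns
    ]
    summary.to_csv(out_dir / "summary.csv", index=False)
    stats_blob = {}
    families = sorted(report.runs["classifier"].unique())
    for eval_set in ("in_domain", "cross_domain"):
        for metric in METRICS:
            try:
                cmp_res = compare_classifiers(report, metric, eval_set)
            except ValueError:
                continue
            stats_blob[f"{eval_set}.{metric}"] = {
                "kruskal_statistic": cmp_res.statistic,
                "kruskal_p": cmp_res.pvalue,
                "undefined": cmp_res.undefined,
                "group_means": cmp_res.group_means,
                "posthoc": None
                if cmp_res.posthoc is None
                else cmp_res.posthoc.to_dict(orient="records"),
            }
    gaps = {}
    for family in families:
        try:
            gap = generalization_gap(report, family)
        except ValueError:
            continue
        gaps[family] = {
            "in_mean": gap.in_mean,
            "cross_mean": gap.cross_mean,
            "drop": gap.drop,
            "p": gap.pvalue,
        }
    stats_blob["generalization_gap.accuracy"] = gaps
    stats_blob["sampen_threshold"] = report.sampen_threshold
    (out_dir / "stats.json").write_text(json.dumps(stats_blob, indent=2, default=float))
    return out_dir
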