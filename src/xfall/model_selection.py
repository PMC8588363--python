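"""Classifier families, sequential backward selection and grid search.

The three classifier families — linear-kernel SVM, k-nearest-neighbours and
random forest — are backed by scikit-learn; this module owns what the
pipeline contributes on top of them: subject-grouped cross-validated
scoring, greedy backward feature selection, exhaustive grid search with
deterministic simplicity-first tie-breaking, and the frozen-model contract
(a fitted model carries its training standardization and feature subset and
never re-tunes on evaluation data).

Sequential backward selection starts from the full feature set and
repeatedly removes the feature whose removal gives the best cross-validated
score, as long as that score does not degrade by more than ``tolerance``
relative to the current score (so equal-score removals — e.g. one of two
duplicated features — are accepted). Ties are broken by removing the
lowest-indexed feature; the subset never shrinks below ``min_features``.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "FAMILIES",
    "ClassifierSpec",
    "HyperparamGrid",
    "TrainedModel",
    "build_estimator",
    "cross_val_accuracy",
    "sequential_backward_selection",
    "grid_search",
    "fit",
]

FAMILIES = ("SVM", "KNN", "RF")

#: Forest size used throughout; modest because the training sets this
#: pipeline sees are small and the grid tunes depth/leaf/split instead.
RF_N_ESTIMATORS = 50


@dataclass
class ClassifierSpec:
    """A classifier family plus concrete hyperparameters.

    SVM: ``C`` (box constraint), ``kernel`` (linear by default).
    KNN: ``k`` (neighbours), ``metric``.
    RF: ``max_split_features``, ``max_levels`` (tree depth), ``min_leaf``.
    """

    family: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")

    @classmethod
    def default(cls, family: str) -> "ClassifierSpec":
        defaults = {
            "SVM": {"C": 1.0, "kernel": "linear"},
            "KNN": {"k": 5, "metric": "minkowski"},
            # Light forest: the default RF spec is what backward selection
            # scores hundreds of candidate subsets with; tree count is not a
            # tuned hyperparameter here.
            "RF": {"max_split_features": 6, "max_levels": 50, "min_leaf": 1,
                   "n_estimators": 15},
        }
        return cls(family, dict(defaults[family]))


def build_estimator(spec: ClassifierSpec, seed: int = 0, n_features: int | None = None):
    """Instantiate the scikit-learn estimator behind a spec."""
    hp = spec.hyperparams
    if spec.family == "SVM":
        return SVC(C=float(hp.get("C", 1.0)), kernel=hp.get("kernel", "linear"))
    if spec.family == "KNN":
        return KNeighborsClassifier(
            n_neighbors=int(hp.get("k", 5)), metric=hp.get("metric", "minkowski")
        )
    max_features = int(hp.get("max_split_features", 6))
    if n_features is not None:
        max_features = max(1, min(max_features, n_features))
    return RandomForestClassifier(
        n_estimators=int(hp.get("n_estimators", RF_N_ESTIMATORS)),
        max_features=max_features,
        max_depth=int(hp["max_levels"]) if hp.get("max_levels") else None,
        min_samples_leaf=int(hp.get("min_leaf", 1)),
        random_state=seed,
    )


def _log_ints(lo: int, hi: int, k: int) -> list[int]:
    vals = np.unique(np.round(np.geomspace(lo, hi, k)).astype(int))
    return [int(v) for v in vals]


@dataclass
class HyperparamGrid:
    """Per-family hyperparameter search spaces (lists of hyperparam dicts)."""

    svm: list[dict] = field(default_factory=list)
    knn: list[dict] = field(default_factory=list)
    rf: list[dict] = field(default_factory=list)

    @classmethod
    def default(cls) -> "HyperparamGrid":
        """Search ranges: SVM C in [0.01, 10] (7 log-spaced points), kNN k in
        [1, 10] (all integers), RF split features in [1, 17], depth in
        [30, 80], leaf size in [1, 48] (4 log-spaced integers per range)."""
        svm = [{"C": float(c), "kernel": "linear"} for c in np.geomspace(0.01, 10.0, 7)]
        knn = [{"k": k, "metric": "minkowski"} for k in range(1, 11)]
        rf = [
            {"max_split_features": f, "max_levels": lv, "min_leaf": ml}
            for f in _log_ints(1, 17, 4)
            for lv in _log_ints(30, 80, 4)
            for ml in _log_ints(1, 48, 4)
        ]
        return cls(svm=svm, knn=knn, rf=rf)

    def for_family(self, family: str) -> list[dict]:
        if family == "SVM":
            return self.svm
        if family == "KNN":
            return self.knn
        if family == "RF":
            return self.rf
        raise ValueError(f"unknown family {family!r}")


def _folds(y, groups, n_folds: int, seed: int):
    """Subject-grouped folds when groups are given, stratified otherwise."""
    y = np.asarray(y)
    if groups is not None:
        groups = np.asarray(groups)
        n_groups = len(np.unique(groups))
        splitter = GroupKFold(n_splits=min(n_folds, n_groups))
        return list(splitter.split(np.zeros(len(y)), y, groups))
    n_per_class = np.bincount(np.unique(y, return_inverse=True)[1]).min()
    splitter = StratifiedKFold(
        n_splits=min(n_folds, n_per_class), shuffle=True, random_state=seed
    )
    return list(splitter.split(np.zeros(len(y)), y))


def cross_val_accuracy(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    groups=None,
    folds: int = 5,
    seed: int = 0,
    fold_indices=None,
) -> float:
    """Mean cross-validated accuracy of a spec on (X, y)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if fold_indices is None:
        fold_indices = _folds(y, groups, folds, seed)
    accs = []
    for train_idx, test_idx in fold_indices:
        if len(np.unique(y[train_idx])) < 2:
            accs.append(0.0)
            continue
        est = build_estimator(spec, seed, n_features=X.shape[1])
        est.fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(est.predict(X[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def sequential_backward_selection(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    groups=None,
    folds: int = 5,
    tolerance: float = 0.0,
    seed: int = 0,
    min_features: int = 1,
) -> np.ndarray:
    """Greedy backward feature selection under a cross-validated accuracy score.

    Returns the sorted indices of the surviving subset (never empty). With
    ``tolerance=0`` the score is non-decreasing along the accepted-removal
    path.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.shape[1] < 2:
        raise ValueError("need at least two features")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    fold_indices = _folds(y, groups, folds, seed)
    current = list(range(X.shape[1]))
    current_score = cross_val_accuracy(
        spec, X, y, folds=folds, seed=seed, fold_indices=fold_indices
    )
    while len(current) > min_features:
        best_j = None
        best_score = -np.inf
        for j, feat in enumerate(current):
            candidate = current[:j] + current[j + 1 :]
            score = cross_val_accuracy(
                spec, X[:, candidate], y, folds=folds, seed=seed, fold_indices=fold_indices
            )
            if score > best_score + 1e-12:
                best_score = score
                best_j = j
        if best_score >= current_score - tolerance:
            del current[best_j]
            current_score = best_score
        else:
            break
    return np.asarray(sorted(current), dtype=int)


def _simplicity_key(family: str, hp: dict) -> tuple:
    """Sort key where smaller = simpler, per family convention."""
    if family == "SVM":
        return (float(hp.get("C", 1.0)),)
    if family == "KNN":
        return (-int(hp.get("k", 5)),)
    return (
        int(hp.get("max_levels", 0) or 0),
        int(hp.get("max_split_features", 0)),
        -int(hp.get("min_leaf", 1)),
    )


def grid_search(
    family: str,
    grid: HyperparamGrid | list[dict],
    X: np.ndarray,
    y: np.ndarray,
    groups=None,
    folds: int = 5,
    seed: int = 0,
) -> ClassifierSpec:
    """Exhaustive grid search by subject-grouped cross-validated accuracy.

    Ties are broken toward the simpler model (smaller C, larger k, shallower
    forest). The returned spec is meant to be frozen for all later
    evaluation sets.
    """
    candidates = grid.for_family(family) if isinstance(grid, HyperparamGrid) else grid
    if not candidates:
        raise ValueError("empty grid")
    fold_indices = _folds(np.asarray(y), groups, folds, seed)
    best_hp = None
    best = (-np.inf, ())
    for hp in candidates:
        spec = ClassifierSpec(family, dict(hp))
        score = cross_val_accuracy(
            spec, X, y, folds=folds, seed=seed, fold_indices=fold_indices
        )
        key = (score, tuple(-v for v in _simplicity_key(family, hp)))
        if key > best:
            best = key
            best_hp = dict(hp)
    return ClassifierSpec(family, best_hp)


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it frozen.

    ``predict`` expects the *raw* (unstandardized) full feature matrix and
    internally applies the stored training standardization and feature
    subset — evaluation on a new dataset can therefore never accidentally
    re-fit either.
    """

    spec: ClassifierSpec
    estimator: object
    selected_features: np.ndarray
    standardization: tuple[np.ndarray, np.ndarray] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.selected_features = np.asarray(self.selected_features, dtype=int)
        if self.selected_features.size == 0:
            raise ValueError("selected_features must be non-empty")

    def transform(self, X_raw: np.ndarray) -> np.ndarray:
        X = np.asarray(X_raw, float)
        if self.standardization is not None:
            mean, sd = self.standardization
            X = (X - mean) / sd
        return X[:, self.selected_features]

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        return self.estimator.predict(self.transform(X_raw))

    def save(self, out_dir) -> Path:
        """Write ``model.json`` (spec + metadata) and a fitted-state blob."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "family": self.spec.family,
            "hyperparams": self.spec.hyperparams,
            "selected_features": self.selected_features.tolist(),
            "standardization": None
            if self.standardization is None
            else [self.standardization[0].tolist(), self.standardization[1].tolist()],
            "provenance": self.provenance,
        }
        (out_dir / "model.json").write_text(json.dumps(meta, indent=2, default=str))
        with open(out_dir / "state.pkl", "wb") as fh:
            pickle.dump(self.estimator, fh)
        return out_dir

    @classmethod
    def load(cls, in_dir) -> "TrainedModel":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "model.json").read_text())
        with open(in_dir / "state.pkl", "rb") as fh:
            estimator = pickle.load(fh)
        std = meta["standardization"]
        return cls(
            spec=ClassifierSpec(meta["family"], meta["hyperparams"]),
            estimator=estimator,
            selected_features=np.asarray(meta["selected_features"], int),
            standardization=None
            if std is None
            else (np.asarray(std[0]), np.asarray(std[1])),
            provenance=meta.get("provenance", {}),
        )


def fit(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    selected_features=None,
    standardization=None,
    provenance: dict | None = None,
) -> TrainedModel:
    """Fit a classifier on (already standardized) training features.

    ``X`` holds the full feature columns; ``selected_features`` (default:
    all) picks the subset actually used. The returned model stores the
    standardization vectors so later predictions reuse them unchanged.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if selected_features is None:
        selected_features = np.arange(X.shape[1])
    selected_features = np.asarray(selected_features, dtype=int)
    est = build_estimator(spec, seed, n_features=selected_features.size)
    est.fit(X[:, selected_features], y)
    return TrainedModel(
        spec=spec,
        estimator=est,
        selected_features=selected_features,
        standardization=standardization,
        provenance=provenance or {},
    )
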