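"""Training, tuning and evaluation of the interaction classifiers.

The protocol: stratified 70/30 train/test split, majority-class
downsampling of every training set (the held-out data is never resampled),
10-fold cross-validation repeated 3 times for tuning, and a small grid per
algorithm family:

========================  =====================  ==========================
algorithm                 tuning parameter(s)    default grid
========================  =====================  ==========================
random_forest             mtry                   2, 21, 200, 421
boosted_logreg            nIter                  11, 21, 31
knn                       k                      5, 7, 9
svm_linear                C                      0.25, 0.5, 1
neural_net                size, decay            1, 3, 5 x 1e-4, 1e-2, 1e-1
========================  =====================  ==========================

``mtry`` is the number of features sampled per split of a random-forest
tree and is clamped to the actual feature count. The boosted logistic
regression is boosting over one-split (stump) weak learners for ``nIter``
rounds. The k-nearest-neighbour distance is Euclidean on the indicator
matrix with all columns min-max scaled to [0, 1] (only the length column is
affected; unscaled, it would dominate the distance). The neural network has
a single logistic-sigmoid hidden layer of ``size`` units with L2 weight
decay ``decay``. The linear-kernel SVM emits margins; probability scores
are a monotone logistic squash of the margin, while AUC is rank-based and
therefore calibration-free.

Model selection within cross-validation uses mean AUC (F1 is reported
alongside). Confusion-matrix metrics are computed at threshold 0.5 on the
interacting-class probability, for either class as reference level.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from scipy.special import expit
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

ALGORITHMS = ("random_forest", "boosted_logreg", "knn", "svm_linear", "neural_net")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"mtry": [2, 21, 200, 421]},
    "boosted_logreg": {"nIter": [11, 21, 31]},
    "knn": {"k": [5, 7, 9]},
    "svm_linear": {"C": [0.25, 0.5, 1.0]},
    "neural_net": {"size": [1, 3, 5], "decay": [1e-4, 1e-2, 1e-1]},
}

REF_INTERACTING = "interacting"
REF_NON_INTERACTING = "non_interacting"


@dataclass(frozen=True)
class ModelSpec:
    """An algorithm family, its tuning grid and the run seed."""

    algorithm: str
    grid: Mapping[str, Sequence] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        grid = dict(self.grid) if self.grid is not None else DEFAULT_GRIDS[self.algorithm]
        if not grid or any(len(v) == 0 for v in grid.values()):
            raise ValueError("grid must be non-empty")
        expected = set(DEFAULT_GRIDS[self.algorithm])
        if set(grid) != expected:
            raise ValueError(
                f"{self.algorithm} expects parameters {sorted(expected)}, "
                f"got {sorted(grid)}"
            )
        object.__setattr__(self, "grid", grid)

    def grid_points(self) -> list[dict]:
        keys = list(self.grid)
        return [
            dict(zip(keys, values))
            for values in itertools.product(*(self.grid[k] for k in keys))
        ]


@dataclass
class EvalMetrics:
    """Thresholded confusion-matrix metrics plus rank-based AUC."""

    precision: float
    recall: float
    f1: float
    auc: float
    accuracy: float
    reference_level: str = REF_INTERACTING

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "accuracy": self.accuracy,
            "reference_level": self.reference_level,
        }


@dataclass
class SplitPlan:
    """A stratified train/test partition with CV fold assignments."""

    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def stratified_split(
    labels: np.ndarray,
    train_frac: float = 0.7,
    seed: int = 0,
    folds: int = 10,
    repeats: int = 3,
) -> SplitPlan:
    """Stratified random split preserving class proportions.

    Samples each class without replacement; the per-class training count is
    ``round(n_class * train_frac)``. Also records the repeated stratified
    CV fold pattern over the training set.
    """
    labels = np.asarray(labels)
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to stratify")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        idx = rng.permutation(idx)
        n_train = int(round(len(idx) * train_frac))
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts))

    fold_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    y_train = labels[train_idx]
    if len(np.unique(y_train)) > 1:
        splitter = RepeatedStratifiedKFold(
            n_splits=folds, n_repeats=repeats, random_state=seed
        )
        for tr, va in splitter.split(np.zeros(len(y_train)), y_train):
            fold_pairs.append((train_idx[tr], train_idx[va]))
    return SplitPlan(seed=seed, train_idx=train_idx, test_idx=test_idx, folds=fold_pairs)


def downsample_majority(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Indices of a class-balanced subset: the minority class in full plus a
    seeded without-replacement subsample of the majority class."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present for downsampling")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep = []
    for cls, count in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        if count > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def build_estimator(algorithm: str, params: Mapping, n_features: int, seed: int):
    """Instantiate the scikit-learn estimator for one grid point."""
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=500,
            max_features=min(int(params["mtry"]), n_features),
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "boosted_logreg":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1, random_state=seed),
            n_estimators=int(params["nIter"]),
            random_state=seed,
        )
    if algorithm == "knn":
        return Pipeline(
            [
                ("scale", MinMaxScaler()),
                ("knn", KNeighborsClassifier(n_neighbors=int(params["k"]))),
            ]
        )
    if algorithm == "svm_linear":
        return SVC(kernel="linear", C=float(params["C"]), random_state=seed)
    if algorithm == "neural_net":
        return MLPClassifier(
            hidden_layer_sizes=(int(params["size"]),),
            activation="logistic",
            alpha=float(params["decay"]),
            solver="lbfgs",  # full-batch quasi-Newton: right fit for tiny nets
            max_iter=2000,
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _scores_from(estimator, X: np.ndarray) -> np.ndarray:
    """Interacting-class probability (or a monotone surrogate) in [0, 1]."""
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(X)
        classes = list(estimator.classes_)
        return proba[:, classes.index(1)]
    return expit(estimator.decision_function(X))


@dataclass
class TrainedClassifier:
    """A fitted model bound to its feature space and provenance."""

    spec: ModelSpec
    chosen_params: dict
    estimator: object
    feature_names: list[str]

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return _scores_from(self.estimator, X)

    def save(self, model_dir: str | Path) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.estimator, model_dir / "estimator.joblib")
        manifest = {
            "format_version": 1,
            "algorithm": self.spec.algorithm,
            "grid": {k: list(v) for k, v in self.spec.grid.items()},
            "seed": self.spec.seed,
            "chosen_params": self.chosen_params,
            "feature_names": self.feature_names,
        }
        (model_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, model_dir: str | Path) -> "TrainedClassifier":
        model_dir = Path(model_dir)
        manifest = json.loads((model_dir / "manifest.json").read_text())
        estimator = joblib.load(model_dir / "estimator.joblib")
        spec = ModelSpec(
            manifest["algorithm"], manifest["grid"], seed=manifest["seed"]
        )
        return cls(spec, manifest["chosen_params"], estimator, manifest["feature_names"])


def metrics_from_scores(
    y_true: np.ndarray,
    scores: np.ndarray,
    threshold: float = 0.5,
    reference_level: str = REF_INTERACTING,
) -> EvalMetrics:
    """Confusion-matrix metrics for the chosen reference class plus AUC.

    AUC is always the probability that a random interacting region scores
    above a random non-interacting one (ties half-weighted); it does not
    depend on the reference level.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined: only one class present")
    auc = float(roc_auc_score(y_true, scores))
    pred = (scores >= threshold).astype(int)
    if reference_level == REF_INTERACTING:
        ref_true, ref_pred = y_true == 1, pred == 1
    elif reference_level == REF_NON_INTERACTING:
        ref_true, ref_pred = y_true == 0, pred == 0
    else:
        raise ValueError(f"unknown reference level {reference_level!r}")
    tp = int(np.sum(ref_true & ref_pred))
    fp = int(np.sum(~ref_true & ref_pred))
    fn = int(np.sum(ref_true & ~ref_pred))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = float(np.mean(pred == y_true))
    return EvalMetrics(precision, recall, f1, auc, accuracy, reference_level)


@dataclass
class CVResult:
    """Mean cross-validated metrics per grid point, best chosen by AUC."""

    per_params: list[tuple[dict, EvalMetrics]]
    best_params: dict
    best_metrics: EvalMetrics


def cross_validate(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    repeats: int = 3,
) -> CVResult:
    """Grid search by repeated stratified k-fold cross-validation.

    Downsampling to class balance is applied inside each training fold,
    never to the held-out fold. Folds whose held-out part contains a single
    class are excluded from the mean with a warning. Deterministic for a
    fixed spec seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=spec.seed
    )
    split_indices = list(splitter.split(X, y))

    per_params: list[tuple[dict, EvalMetrics]] = []
    for params in spec.grid_points():
        fold_metrics: list[EvalMetrics] = []
        n_excluded = 0
        for fold_i, (tr, va) in enumerate(split_indices):
            if len(np.unique(y[va])) < 2:
                n_excluded += 1
                continue
            bal = downsample_majority(y[tr], seed_for(spec.seed, fold_i))
            tr_bal = tr[bal]
            est = build_estimator(spec.algorithm, params, X.shape[1], spec.seed)
            est.fit(X[tr_bal], y[tr_bal])
            fold_metrics.append(metrics_from_scores(y[va], _scores_from(est, X[va])))
        if n_excluded:
            logger.warning(
                "%s %s: %d single-class held-out folds excluded",
                spec.algorithm,
                params,
                n_excluded,
            )
        if not fold_metrics:
            raise ValueError("no usable folds: held-out data always single-class")
        mean = EvalMetrics(
            precision=float(np.mean([m.precision for m in fold_metrics])),
            recall=float(np.mean([m.recall for m in fold_metrics])),
            f1=float(np.mean([m.f1 for m in fold_metrics])),
            auc=float(np.mean([m.auc for m in fold_metrics])),
            accuracy=float(np.mean([m.accuracy for m in fold_metrics])),
        )
        per_params.append((params, mean))

    best_params, best_metrics = max(per_params, key=lambda pm: pm[1].auc)
    return CVResult(per_params, best_params, best_metrics)


def seed_for(seed: int, stream: int) -> int:
    """Derive a deterministic sub-seed below 2**31."""
    return (seed * 9973 + stream * 7919 + 17) % (2**31 - 1)


def train_final(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    chosen_params: Mapping,
    feature_names: Sequence[str] | None = None,
) -> TrainedClassifier:
    """Fit the chosen grid point on the downsampled training set."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    bal = downsample_majority(y_train, seed_for(spec.seed, 10_000))
    est = build_estimator(spec.algorithm, chosen_params, X_train.shape[1], spec.seed)
    try:
        est.fit(X_train[bal], y_train[bal])
    except Exception as exc:  # pragma: no cover - degenerate fits
        raise RuntimeError(f"{spec.algorithm}: fit failed: {exc}") from exc
    names = list(feature_names) if feature_names is not None else [
        f"x{i}" for i in range(X_train.shape[1])
    ]
    return TrainedClassifier(spec, dict(chosen_params), est, names)


def evaluate(
    classifier: TrainedClassifier,
    X_test: np.ndarray,
    y_test: np.ndarray,
    threshold: float = 0.5,
    reference_level: str = REF_INTERACTING,
) -> EvalMetrics:
    """Test-set metrics of a trained classifier at the given threshold."""
    scores = classifier.predict_scores(np.asarray(X_test, dtype=float))
    return metrics_from_scores(y_test, scores, threshold, reference_level)


def evaluate_both_orientations(
    classifier: TrainedClassifier,
    X_test: np.ndarray,
    y_test: np.ndarray,
    threshold: float = 0.5,
) -> dict[str, EvalMetrics]:
    """Metrics with each class as the reference level (same AUC)."""
    scores = classifier.predict_scores(np.asarray(X_test, dtype=float))
    return {
        ref: metrics_from_scores(y_test, scores, threshold, ref)
        for ref in (REF_INTERACTING, REF_NON_INTERACTING)
    }


def variable_importance(classifier: TrainedClassifier) -> list[tuple[str, float]]:
    """Random-forest variable importance rescaled so the top feature is 100.

    Returns (feature_name, importance) sorted by decreasing importance.
    With all-constant features every importance is zero and the zeros are
    returned unscaled. Only supported for random forests.
    """
    if classifier.spec.algorithm != "random_forest":
        raise ValueError(
            f"variable importance requires a random forest, "
            f"got {classifier.spec.algorithm}"
        )
    raw = np.asarray(classifier.estimator.feature_importances_, dtype=float)
    top = raw.max()
    scaled = raw * (100.0 / top) if top > 0 else raw
    order = np.argsort(-scaled, kind="stable")
    return [(classifier.feature_names[i], float(scaled[i])) for i in order]


@dataclass
class WindowSearchResult:
    """AUC per symmetric context half-width and the selected width."""

    auc_by_n: dict[int, float]
    best_n: int


def optimize_context_window(
    matrices_by_n: Mapping[int, tuple[np.ndarray, np.ndarray]],
    spec: ModelSpec,
    folds: int = 10,
    repeats: int = 3,
) -> WindowSearchResult:
    """Pick the symmetric context half-width N with the best CV AUC.

    ``matrices_by_n`` maps each candidate N to its encoded (X, y). Ties are
    broken toward the smaller N (the simpler model).
    """
    auc_by_n: dict[int, float] = {}
    for n in sorted(matrices_by_n):
        X, y = matrices_by_n[n]
        result = cross_validate(spec, X, y, folds=folds, repeats=repeats)
        auc_by_n[n] = result.best_metrics.auc
    best_n = min(sorted(auc_by_n), key=lambda n: (-auc_by_n[n], n))
    return WindowSearchResult(auc_by_n, best_n)
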