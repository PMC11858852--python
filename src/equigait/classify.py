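"""Class-weighted RBF support-vector classification with bootstrap validation.

The classifier follows a fixed protocol: standardize features (center, scale
to unit sample SD), weight classes by N/(K*n_c) to balance predictions across
the K=5 groups, fit an RBF-kernel SVM (K(x, x') = exp(-sigma * ||x - x'||^2),
one-vs-one multiclass voting) with the cost parameter tuned over a doubling
grid 0.25..128 at fixed sigma = 0.036, and validate the selected model by
bootstrap resampling: each repetition refits the full pipeline on a resample
drawn with replacement and scores the out-of-bag rows.

The ``sigma`` here equals the ``gamma`` of scikit-learn's SVC (both
parameterize exp(-g * ||x - x'||^2)); no conversion is needed.

Variable importance is model-agnostic filter importance: for every feature
and class, the ROC AUC of the raw feature separating that class from the
rest, folded as max(AUC, 1 - AUC), then min-max rescaled globally to 0-100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .reference import CLASS_ORDER

logger = logging.getLogger(__name__)

DEFAULT_COST_GRID: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)


@dataclass(frozen=True)
class SVMConfig:
    """Protocol parameters of the classifier."""

    sigma: float = 0.036
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    class_weight_mode: str = "balanced"  # balanced | none | custom
    custom_weights: dict[str, float] | None = None
    bootstrap_reps: int = 400
    tuning_reps: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cost_grid", tuple(float(c) for c in self.cost_grid))

    def validate(self) -> None:
        grid = np.asarray(self.cost_grid, dtype=float)
        if len(grid) == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("cost_grid must be strictly increasing and positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.bootstrap_reps < 1 or self.tuning_reps < 1:
            raise ValueError("bootstrap repetitions must be >= 1")
        if self.class_weight_mode not in ("balanced", "none", "custom"):
            raise ValueError(f"unknown class_weight_mode {self.class_weight_mode!r}")


@dataclass
class StandardizationParams:
    center: pd.Series
    scale: pd.Series


def standardize(features: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Center and scale each column to mean 0, sample SD 1 (ddof=1)."""
    if len(features) < 2:
        raise ValueError("standardization needs >= 2 rows")
    values = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("features contain non-finite values")
    center = features.mean(axis=0)
    scale = features.std(axis=0, ddof=1)
    zero = scale[scale == 0.0]
    if len(zero):
        raise ValueError(f"zero-variance feature(s): {list(zero.index)}")
    params = StandardizationParams(center=center, scale=scale)
    return apply_standardization(features, params), params


def apply_standardization(features: pd.DataFrame, params: StandardizationParams) -> pd.DataFrame:
    return (features - params.center) / params.scale


def class_weights(y, mode: str = "balanced", custom: dict[str, float] | None = None) -> dict[str, float]:
    """Per-class weights w_c = N / (K * n_c) in balanced mode (K = number of
    classes present), all ones in none mode."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty label vector")
    classes, counts = np.unique(y, return_counts=True)
    if mode == "none":
        return {str(c): 1.0 for c in classes}
    if mode == "custom":
        if custom is None:
            raise ValueError("custom mode requires explicit weights")
        return dict(custom)
    if mode != "balanced":
        raise ValueError(f"unknown mode {mode!r}")
    n, k = len(y), len(classes)
    return {str(c): n / (k * cnt) for c, cnt in zip(classes, counts)}


@dataclass
class TrainedModel:
    """Fitted standardize -> weight -> RBF-SVM pipeline with tuning metadata."""

    svc: SVC
    standardization: StandardizationParams
    cost: float
    sigma: float
    weights: dict[str, float]
    feature_names: tuple[str, ...]
    grid_results: dict[float, float]  # cost -> mean out-of-bag tuning accuracy
    config: SVMConfig
    seed: int

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        scaled = apply_standardization(features[list(self.feature_names)], self.standardization)
        return self.svc.predict(scaled.to_numpy(dtype=float))

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        return joblib.load(path)


def _fit_svc(X: np.ndarray, y: np.ndarray, cost: float, sigma: float,
             weights: dict[str, float]) -> SVC:
    # SVC is one-vs-one for multiclass, matching the intended voting scheme
    svc = SVC(C=cost, kernel="rbf", gamma=sigma, class_weight=weights)
    svc.fit(X, y)
    return svc


def _bootstrap_split(rng: np.random.Generator, y: np.ndarray,
                     required: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Indices drawn with replacement plus the out-of-bag rows; resamples
    missing a class (or with an empty bag) are redrawn."""
    n = len(y)
    redraws = 0
    while True:
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) and len(np.unique(y[idx])) == len(required):
            return idx, oob, redraws
        redraws += 1


def _resample_standardize(X: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = X[idx].mean(axis=0)
    scale = X[idx].std(axis=0, ddof=1)
    scale[scale == 0.0] = 1.0  # guard: a degenerate resample column stays centered
    return center, scale


def train_svm(X: pd.DataFrame, y, config: SVMConfig | None = None) -> TrainedModel:
    """Tune the cost by bootstrap out-of-bag accuracy, then refit on all data.

    Each tuning repetition draws one resample and scores every cost on the
    same out-of-bag rows (paired comparison); the cost with the highest mean
    accuracy wins, ties going to the smallest cost.  The returned model is
    refit on the full data with class weights.
    """
    config = config or SVMConfig()
    config.validate()
    y = np.asarray([str(v) for v in y])
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer than 2 members")

    Xv = X.to_numpy(dtype=float)
    tune_ss, _ = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(tune_ss)
    grid_acc: dict[float, list[float]] = {c: [] for c in config.cost_grid}
    total_redraws = 0
    for _ in range(config.tuning_reps):
        idx, oob, redraws = _bootstrap_split(rng, y, classes)
        total_redraws += redraws
        center, scale = _resample_standardize(Xv, idx)
        Xs_train = (Xv[idx] - center) / scale
        Xs_oob = (Xv[oob] - center) / scale
        weights = class_weights(y[idx], config.class_weight_mode, config.custom_weights)
        for cost in config.cost_grid:
            svc = _fit_svc(Xs_train, y[idx], cost, config.sigma, weights)
            grid_acc[cost].append(float(np.mean(svc.predict(Xs_oob) == y[oob])))
    if total_redraws:
        logger.info("tuning: %d resamples redrawn for missing classes", total_redraws)
    grid_results = {cost: float(np.mean(accs)) for cost, accs in grid_acc.items()}
    best_acc = max(grid_results.values())
    cost = next(c for c in config.cost_grid if grid_results[c] == best_acc)

    features_df = X.copy()
    scaled, params = standardize(features_df)
    weights = class_weights(y, config.class_weight_mode, config.custom_weights)
    svc = _fit_svc(scaled.to_numpy(dtype=float), y, cost, config.sigma, weights)
    return TrainedModel(
        svc=svc,
        standardization=params,
        cost=cost,
        sigma=config.sigma,
        weights=weights,
        feature_names=tuple(X.columns),
        grid_results=grid_results,
        config=config,
        seed=config.seed,
    )


@dataclass
class BootstrapSummary:
    """Out-of-bag validation over B bootstrap repetitions."""

    accuracies: np.ndarray  # per-repetition overall OOB accuracy
    per_class_mean: dict[str, float]
    confusion_counts: pd.DataFrame  # OOB predictions aggregated over reps
    redraws: int
    cost: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    @property
    def macro_accuracy(self) -> float:
        """Mean of per-class OOB accuracies (classes equally weighted)."""
        return float(np.mean(list(self.per_class_mean.values())))


def bootstrap_validate(X: pd.DataFrame, y, config: SVMConfig | None = None,
                       cost: float | None = None, reps: int | None = None) -> BootstrapSummary:
    """Seeded bootstrap validation of the full pipeline at a fixed cost.

    Every repetition refits standardization, weights and the SVM on a
    resample and evaluates the out-of-bag rows.  Resamples missing a class
    are redrawn (counted in ``redraws``).  Bit-for-bit reproducible per seed.
    """
    config = config or SVMConfig()
    config.validate()
    if cost is None:
        cost = 1.0
    y = np.asarray([str(v) for v in y])
    classes = np.unique(y)
    order = [c for c in CLASS_ORDER if c in classes] + sorted(set(classes) - set(CLASS_ORDER))
    Xv = X.to_numpy(dtype=float)
    _, val_ss = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(val_ss)
    B = config.bootstrap_reps if reps is None else int(reps)

    accuracies = np.empty(B)
    per_class: dict[str, list[float]] = {c: [] for c in order}
    agg = np.zeros((len(order), len(order)), dtype=int)
    total_redraws = 0
    for b in range(B):
        idx, oob, redraws = _bootstrap_split(rng, y, classes)
        total_redraws += redraws
        center, scale = _resample_standardize(Xv, idx)
        weights = class_weights(y[idx], config.class_weight_mode, config.custom_weights)
        svc = _fit_svc((Xv[idx] - center) / scale, y[idx], cost, config.sigma, weights)
        pred = svc.predict((Xv[oob] - center) / scale)
        truth = y[oob]
        accuracies[b] = float(np.mean(pred == truth))
        for c in order:
            mask = truth == c
            if mask.any():
                per_class[c].append(float(np.mean(pred[mask] == c)))
        agg += _sk_confusion_matrix(truth, pred, labels=order)
    if total_redraws:
        logger.info("validation: %d resamples redrawn for missing classes", total_redraws)
    return BootstrapSummary(
        accuracies=accuracies,
        per_class_mean={c: float(np.mean(v)) for c, v in per_class.items()},
        confusion_counts=pd.DataFrame(agg, index=order, columns=order),
        redraws=total_redraws,
        cost=float(cost),
    )


@dataclass
class ConfusionMatrix:
    """5x5 confusion matrix (rows actual, columns predicted) with percents."""

    counts: pd.DataFrame
    row_percent: pd.DataFrame
    per_class_accuracy: dict[str, float]  # %
    overall_accuracy: float  # %


def confusion_and_accuracy(y_true, y_pred, class_order=CLASS_ORDER) -> ConfusionMatrix:
    y_true = np.asarray([str(v) for v in y_true])
    y_pred = np.asarray([str(v) for v in y_pred])
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    unknown = (set(y_true) | set(y_pred)) - set(class_order)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    counts = _sk_confusion_matrix(y_true, y_pred, labels=list(class_order))
    return confusion_from_counts(counts, class_order)


def confusion_from_counts(counts, class_order=CLASS_ORDER) -> ConfusionMatrix:
    """Build the full report from a counts matrix (rows actual, cols predicted)."""
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("confusion counts must be square")
    if counts.shape[0] != len(class_order):
        raise ValueError("counts do not match the class order")
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums[:, None] > 0, 100.0 * counts / row_sums[:, None], 0.0)
    per_class = {
        c: (100.0 * counts[i, i] / row_sums[i]) if row_sums[i] else float("nan")
        for i, c in enumerate(class_order)
    }
    overall = 100.0 * np.trace(counts) / counts.sum()
    idx = list(class_order)
    return ConfusionMatrix(
        counts=pd.DataFrame(counts, index=idx, columns=idx),
        row_percent=pd.DataFrame(pct, index=idx, columns=idx),
        per_class_accuracy=per_class,
        overall_accuracy=float(overall),
    )


def variable_importance(X: pd.DataFrame, y, class_order=CLASS_ORDER) -> pd.DataFrame:
    """Filter (ROC-based) one-vs-rest importance, min-max scaled to 0-100.

    For each feature and class, AUC of the raw feature separating the class
    from the rest, folded as max(AUC, 1-AUC); the feature x class matrix is
    rescaled so its global maximum is 100 and its minimum 0.  A constant
    feature discriminates nothing (folded AUC 0.5, the scale minimum).
    """
    y = np.asarray([str(v) for v in y])
    classes = [c for c in class_order if c in set(y)]
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for importance")
    raw = pd.DataFrame(index=list(X.columns), columns=classes, dtype=float)
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        if np.all(x == x[0]):
            logger.debug("feature %s is constant; importance set to the scale minimum", name)
            raw.loc[name] = 0.5
            continue
        for c in classes:
            auc = roc_auc_score((y == c).astype(int), x)
            raw.loc[name, c] = max(auc, 1.0 - auc)
    lo, hi = float(raw.min().min()), float(raw.max().max())
    if hi == lo:
        return raw * 0.0
    return 100.0 * (raw - lo) / (hi - lo)
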