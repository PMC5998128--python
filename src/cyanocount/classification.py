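"""Component classification: threshold rule cascade and quadratic-kernel SVM.

Two-species mode uses a three-feature rule cascade on eccentricity ε,
compactness c and area a:

    C_A (filamentous)   iff  ε >= ω  and  c <= τ  and  ψ_AL <= a <= ψ_AU
    C_M (unicellular)   iff  ε <  ω  and  c >  τ  and  ψ_ML <= a <= ψ_MU
    C_N (neither)       otherwise

with the boundary inclusivities exactly as written (the ε and c conjuncts
of the two branches are complementary, so the branches are disjoint by
construction).  The default boundaries ω = 0.70 and τ = 0.80 sit midway
between representative feature values of the two cyanobacteria
(*Anabaena* ε ≈ 0.85, c ≈ 0.64; *Microcystis* ε ≈ 0.52, c ≈ 0.98); the
area windows ψ are derived from the calibrated unit-cell area.

Three-species mode (adding the spindle-shaped green alga *Ankistrodesmus*)
uses a support vector machine with an inhomogeneous quadratic polynomial
kernel on the full seven-feature vector, with per-column standardization
fitted on the training folds and stratified five-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ContractError, UndefinedMetricWarning
from .morphology import ComponentFeatures

DEFAULT_OMEGA = 0.70
DEFAULT_TAU = 0.80

#: Canonical order of the seven morphological features.
FEATURE_NAMES = (
    "area", "eccentricity", "compactness", "convex_area",
    "solidity", "extent", "perimeter",
)

MODEL_FORMAT_VERSION = 1


class ClassLabel(Enum):
    """Component classes: two cyanobacteria, one alga, or neither."""

    ANABAENA = "A"
    MICROCYSTIS = "M"
    ANKISTRODESMUS = "K"
    NONE = "N"


@dataclass
class RuleThresholds:
    """The six decision boundaries of the rule cascade.

    ``omega``/``tau`` bound eccentricity and compactness; ``psi_al``/
    ``psi_au`` and ``psi_ml``/``psi_mu`` are the area windows (px²) for the
    filamentous and unicellular class respectively.
    """

    omega: float = DEFAULT_OMEGA
    tau: float = DEFAULT_TAU
    psi_al: float = 0.0
    psi_au: float = np.inf
    psi_ml: float = 0.0
    psi_mu: float = np.inf

    def __post_init__(self) -> None:
        if not 0 <= self.omega <= 1:
            raise ContractError("omega must lie in [0, 1]")
        if not self.tau > 0:
            raise ContractError("tau must be positive")
        if self.psi_al > self.psi_au or self.psi_ml > self.psi_mu:
            raise ContractError("area bounds must satisfy lower <= upper")

    @classmethod
    def from_unit_areas(
        cls,
        unit_area_m_px: float,
        unit_area_a_px: float,
        omega: float = DEFAULT_OMEGA,
        tau: float = DEFAULT_TAU,
        lower: float = 0.25,
        upper: float = 4.0,
        max_filament_cells: int = 64,
    ) -> "RuleThresholds":
        """Derive area windows from calibrated unit-cell areas (px²).

        The unicellular window spans ``[lower, upper]`` × the unit-cell
        area.  The filamentous upper bound instead spans
        ``max_filament_cells`` unit cells, because one connected component
        is a whole filament comprising many cells.
        """
        return cls(
            omega=omega, tau=tau,
            psi_al=lower * unit_area_a_px,
            psi_au=max_filament_cells * unit_area_a_px,
            psi_ml=lower * unit_area_m_px,
            psi_mu=upper * unit_area_m_px,
        )


def classify_rule(
    features: ComponentFeatures, thresholds: RuleThresholds
) -> ClassLabel:
    """Assign one component to {C_A, C_M, C_N} by the threshold cascade."""
    eps, c, a = features.eccentricity, features.compactness, features.area_px
    t = thresholds
    if eps >= t.omega and c <= t.tau and t.psi_al <= a <= t.psi_au:
        return ClassLabel.ANABAENA
    if eps < t.omega and c > t.tau and t.psi_ml <= a <= t.psi_mu:
        return ClassLabel.MICROCYSTIS
    return ClassLabel.NONE


def classify_rule_all(
    features: list[ComponentFeatures], thresholds: RuleThresholds
) -> list[ClassLabel]:
    return [classify_rule(f, thresholds) for f in features]


@dataclass
class ConfusionMatrix:
    """K×K count table; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ContractError("counts must be K x K for K class names")
        if (self.counts < 0).any():
            raise ContractError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise ContractError("empty confusion matrix")
        return float(np.trace(self.counts) / self.total)

    @classmethod
    def from_labels(cls, true, pred, class_names=None) -> "ConfusionMatrix":
        true = [getattr(t, "value", t) for t in true]
        pred = [getattr(p, "value", p) for p in pred]
        if class_names is None:
            class_names = sorted(set(true) | set(pred))
        index = {c: i for i, c in enumerate(class_names)}
        counts = np.zeros((len(class_names),) * 2, dtype=np.int64)
        for t, p in zip(true, pred, strict=True):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, class_names=list(class_names))


@dataclass
class BinaryMetrics:
    """One-vs-rest evaluation metrics for a chosen positive class.

    ``sensitivity`` is TP/(TP+FN), identical to recall.  Ratios with a
    zero denominator are reported as NaN (with a warning), never as 0.
    """

    specificity: float
    sensitivity: float
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "specificity": self.specificity, "sensitivity": self.sensitivity,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
        }


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)",
                      UndefinedMetricWarning, stacklevel=3)
        return float("nan")
    return num / den


def metrics(matrix: ConfusionMatrix, positive_class: str) -> BinaryMetrics:
    """Specificity, sensitivity, accuracy, precision, recall and F1 for
    ``positive_class`` under a one-vs-rest reduction of the matrix."""
    if matrix.total == 0:
        raise ContractError("empty confusion matrix")
    positive_class = getattr(positive_class, "value", positive_class)
    if positive_class not in matrix.class_names:
        raise ContractError(f"class {positive_class!r} not in matrix")
    i = matrix.class_names.index(positive_class)
    counts = matrix.counts
    tp = float(counts[i, i])
    fn = float(counts[i, :].sum() - tp)
    fp = float(counts[:, i].sum() - tp)
    tn = float(counts.sum() - tp - fn - fp)
    precision = _safe_ratio(tp, tp + fp, "precision")
    recall = _safe_ratio(tp, tp + fn, "recall")
    f1 = (
        _safe_ratio(2 * precision * recall, precision + recall, "F1")
        if np.isfinite(precision) and np.isfinite(recall)
        else float("nan")
    )
    return BinaryMetrics(
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
        sensitivity=recall,
        accuracy=(tn + tp) / (tp + tn + fp + fn),
        precision=precision,
        recall=recall,
        f1=f1,
    )


def macro_average(matrix: ConfusionMatrix) -> BinaryMetrics:
    """Unweighted mean of per-class one-vs-rest metrics."""
    per = [metrics(matrix, c).as_dict() for c in matrix.class_names]
    agg = {k: float(np.mean([p[k] for p in per])) for k in per[0]}
    return BinaryMetrics(**agg)


@dataclass
class SvmModel:
    """Fitted standardize+SVM pipeline with its provenance."""

    pipeline: Pipeline
    classes: list[str]
    kernel_degree: int
    seed: int
    format_version: int = MODEL_FORMAT_VERSION

    def predict(self, X: np.ndarray) -> list[str]:
        return list(self.pipeline.predict(_validate_features(X)))


def _validate_features(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise ContractError(
            f"feature table must have {len(FEATURE_NAMES)} columns "
            f"({', '.join(FEATURE_NAMES)})"
        )
    if not np.isfinite(X).all():
        raise ContractError("non-finite feature value")
    return X


def _make_pipeline(kernel_degree: int) -> Pipeline:
    # coef0=1 gives the full (inhomogeneous) quadratic kernel
    # (gamma <x, y> + 1)^degree; one-vs-one multiclass, C = 1.
    return make_pipeline(
        StandardScaler(),
        SVC(kernel="poly", degree=kernel_degree, C=1.0, coef0=1.0,
            gamma="scale"),
    )


def train_svm(
    X: np.ndarray, y, kernel_degree: int = 2, seed: int = 0
) -> SvmModel:
    """Fit the quadratic-kernel SVM on a labelled 7-feature table.

    Features are z-scored per column before kernel evaluation; the fitted
    standardization is stored inside the model.  Deterministic given the
    seed (the quadratic SVM fit itself is deterministic; the seed is kept
    for provenance and fold shuffling downstream).
    """
    X = _validate_features(X)
    y = np.asarray([getattr(v, "value", v) for v in y])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ContractError("training set must contain at least two classes")
    if X.shape[0] < 2 * len(classes):
        raise ContractError("need at least 2 instances per class")
    pipe = _make_pipeline(kernel_degree)
    pipe.fit(X, y)
    return SvmModel(pipeline=pipe, classes=classes,
                    kernel_degree=kernel_degree, seed=seed)


@dataclass
class CVResult:
    accuracy: float
    matrix: ConfusionMatrix


def cross_validate(
    X: np.ndarray, y, k: int = 5, seed: int = 0, kernel_degree: int = 2
) -> CVResult:
    """Stratified k-fold cross-validation of the quadratic-kernel SVM.

    Every instance is predicted exactly once by a model trained on the
    other folds; the pooled confusion matrix and its overall accuracy
    (trace / total) are returned.
    """
    if k < 2:
        raise ContractError("k must be >= 2")
    X = _validate_features(X)
    y = np.asarray([getattr(v, "value", v) for v in y])
    classes, counts = np.unique(y, return_counts=True)
    for cls, n in zip(classes, counts):
        if n < k:
            raise ContractError(
                f"class {cls!r} has only {n} members; needs >= k = {k}"
            )
    pred = np.empty_like(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        pipe = _make_pipeline(kernel_degree)
        pipe.fit(X[train_idx], y[train_idx])
        pred[test_idx] = pipe.predict(X[test_idx])
    matrix = ConfusionMatrix.from_labels(y, pred, class_names=list(classes))
    return CVResult(accuracy=matrix.accuracy, matrix=matrix)


def save_model(model: SvmModel, path: str | Path) -> None:
    """Persist a fitted model (kernel spec, support vectors and
    standardization parameters) with a format-version stamp."""
    joblib.dump(
        {"format_version": MODEL_FORMAT_VERSION, "model": model}, Path(path)
    )


def load_model(path: str | Path) -> SvmModel:
    payload = joblib.load(Path(path))
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ContractError(
            f"unsupported model format version {payload.get('format_version')}"
        )
    return payload["model"]
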