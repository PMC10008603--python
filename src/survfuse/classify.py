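"""Classifier roster and the stratified cross-validation protocol.

Five classifiers — RBF / linear / polynomial / sigmoid soft-margin SVMs and a
random forest — evaluated with ten-fold stratified cross-validation.  The
training portion of every fold is balanced by upsampling the minority class
with replacement; test folds are never touched.  Metrics follow the clinical
convention that the short-term survivor (label 1) is the positive class:
a short-term patient predicted short-term is a true positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .containers import ConfigError, ValidationError

CLASSIFIER_KINDS = ("rbf_svm", "linear_svm", "polynomial_svm", "sigmoid_svm", "random_forest")

_KERNELS = {"rbf_svm": "rbf", "linear_svm": "linear", "polynomial_svm": "poly", "sigmoid_svm": "sigmoid"}


@dataclass
class ClassifierSpec:
    """Configuration of one roster member.

    ``C`` is the soft-margin penalty (small by design, favouring wide
    margins); gamma follows the reciprocal-of-feature-count rule so larger
    fused feature spaces get smoother decision boundaries.
    """

    kind: str = "rbf_svm"
    C: float = 0.1
    degree: int = 3
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigError(f"unknown classifier kind {self.kind!r}")
        if self.C <= 0:
            raise ConfigError(f"C must be positive, got {self.C}")
        if self.degree < 2:
            raise ConfigError(f"degree must be >= 2, got {self.degree}")
        if self.n_trees < 1:
            raise ConfigError(f"n_trees must be >= 1, got {self.n_trees}")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    acc: float
    pre: float
    sn: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "pre": self.pre, "sn": self.sn, "f1": self.f1}


@dataclass
class EvalResult:
    """Per-fold metrics plus their across-fold mean and population std."""

    folds: list[MetricSet]
    spec: ClassifierSpec | None = None
    feature_kind: str | None = None
    counts: list[ConfusionCounts] = field(default_factory=list)

    def mean(self) -> MetricSet:
        return MetricSet(*(float(np.mean([getattr(f, k) for f in self.folds])) for k in ("acc", "pre", "sn", "f1")))

    def std(self) -> MetricSet:
        return MetricSet(*(float(np.std([getattr(f, k) for f in self.folds])) for k in ("acc", "pre", "sn", "f1")))


def make_stratified_folds(labels: np.ndarray, n_folds: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Seeded stratified partition; returns the test-index array per fold."""
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("stratified folds require both classes present")
    if counts.min() < n_folds:
        raise ValidationError(
            f"smallest class has {counts.min()} members, fewer than n_folds={n_folds}"
        )
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros((len(labels), 1)), labels)]


def upsample_minority(
    X: np.ndarray, y: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Resample minority rows with replacement until the classes balance."""
    X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("upsampling requires both classes in the training set")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    deficit = int(abs(counts[0] - counts[1]))
    pool = np.flatnonzero(y == minority)
    extra = np.random.default_rng(seed).choice(pool, size=deficit, replace=True)
    return np.vstack([X, X[extra]]), np.concatenate([y, y[extra]])


def build_classifier(spec: ClassifierSpec, n_features: int):
    """Instantiate the configured sklearn estimator (gamma = 1/n_features)."""
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees, max_features="sqrt", random_state=spec.seed
        )
    return SVC(
        kernel=_KERNELS[spec.kind],
        C=spec.C,
        gamma=1.0 / n_features,
        degree=spec.degree,
        coef0=0.0,
    )


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Cell counts with short-term survivor (label 1) as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("label vectors differ in length")
    for v in (y_true, y_pred):
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: 0/0 defined as 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Acc, Pre, Sn and f1 from the four cells (0/0 -> 0 with a warning)."""
    if c.total == 0:
        raise ValidationError("empty confusion counts")
    acc = (c.tp + c.tn) / c.total
    pre = _safe_div(c.tp, c.tp + c.fp, "precision")
    sn = _safe_div(c.tp, c.tp + c.fn, "sensitivity")
    f1 = _safe_div(2 * pre * sn, pre + sn, "f1")
    return MetricSet(acc=acc, pre=pre, sn=sn, f1=f1)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    n_folds: int = 10,
    seed: int = 0,
    transform_factory=None,
) -> EvalResult:
    """Ten-fold stratified CV with per-fold minority upsampling.

    ``transform_factory(X_train) -> transform`` enables leakage-safe
    ("per-fold") feature reduction: the returned callable is applied to both
    the balanced training fold and the untouched test fold.  With the default
    ``None`` the features are used as passed (reducers already fitted on the
    full cohort before CV).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("features and labels are not aligned")
    folds = make_stratified_folds(y, n_folds=n_folds, seed=seed)
    results, counts = [], []
    all_test = np.concatenate(folds)
    assert len(all_test) == len(y) and len(np.unique(all_test)) == len(y)
    for i, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        assert not np.intersect1d(np.flatnonzero(train_mask), test_idx).size
        X_tr, y_tr = X[train_mask], y[train_mask]
        X_te, y_te = X[test_idx], y[test_idx]
        if transform_factory is not None:
            transform = transform_factory(X_tr)
            X_tr, X_te = transform(X_tr), transform(X_te)
        X_tr, y_tr = upsample_minority(X_tr, y_tr, seed=seed + i)
        clf = build_classifier(spec, X.shape[1] if transform_factory is None else X_tr.shape[1])
        clf.fit(X_tr, y_tr)
        c = confusion_counts(y_te, clf.predict(X_te))
        counts.append(c)
        results.append(compute_metrics(c))
    return EvalResult(folds=results, spec=spec, counts=counts)
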