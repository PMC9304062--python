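"""Pixel-based classification of striatal image features.

Three classifier families — logistic regression (LR), k-nearest neighbours
(kNN) and gradient boosted trees (GBT) — are trained directly on the 4900
pixel values of the standardized 70x70 image, with no engineered features.
Each binary visual feature (low uptake, asymmetry, dot-like shape, overall
abnormality) gets its own classifier emitting a probability in [0, 1].

Evaluation follows a fourfold cross-validation: subjects are split 75%/25%
into training and validation folds before augmentation, horizontally flipped
copies double the training folds only, and the pooled out-of-fold
probabilities yield recall, precision, F1, accuracy and AUC.  The AUC is the
Mann-Whitney probability that a random positive outranks a random negative
(ties counted 1/2), with a two-sided test against 0.5.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .preprocess import augment_flip
from .types import StandardImage

__all__ = [
    "ClassifierSpec",
    "FeatureProbabilitySet",
    "MetricsReport",
    "train_classifier",
    "predict_proba",
    "crossvalidate_fourfold",
    "compute_metrics",
    "auc_mann_whitney",
    "DEFAULT_SPECS",
]

METHODS = ("lr", "knn", "gbt")


@dataclass(frozen=True)
class ClassifierSpec:
    """Method name plus explicit hyperparameters.

    Defaults: LR is L2-regularized (C=1); kNN uses k=5 with Euclidean
    distance on the raw pixel vectors; GBT grows 200 depth-3 trees at
    learning rate 0.1, examining sqrt(4900) = 70 candidate pixels per split.
    """

    method: str = "lr"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        hp = self.hyperparameters
        if self.method == "knn" and hp.get("n_neighbors", 5) < 1:
            raise ValueError("kNN needs n_neighbors >= 1")
        if self.method == "gbt" and hp.get("n_estimators", 200) < 1:
            raise ValueError("GBT needs n_estimators >= 1")

    def make_estimator(self):
        hp = dict(self.hyperparameters)
        if self.method == "lr":
            return LogisticRegression(C=hp.pop("C", 1.0), solver="lbfgs",
                                      max_iter=hp.pop("max_iter", 2000), **hp)
        if self.method == "knn":
            return KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5),
                                        metric=hp.pop("metric", "euclidean"), **hp)
        return GradientBoostingClassifier(
            n_estimators=hp.pop("n_estimators", 200),
            max_depth=hp.pop("max_depth", 3),
            learning_rate=hp.pop("learning_rate", 0.1),
            max_features=hp.pop("max_features", "sqrt"),
            random_state=self.seed, **hp)


DEFAULT_SPECS = {m: ClassifierSpec(method=m) for m in METHODS}


@dataclass
class FeatureProbabilitySet:
    """Classifier probabilities for the four features of one image."""

    p_low: float
    p_asym: float
    p_dot: float
    p_abnormal: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")


@dataclass
class MetricsReport:
    """Threshold metrics plus AUC for one classifier/feature combination."""

    auc: float
    recall: float
    precision: float
    f1_score: float
    accuracy: float
    p_value: float
    threshold: float = 0.5
    per_fold: list = field(default_factory=list)


def _as_matrix(images: Sequence) -> np.ndarray:
    rows = []
    shape = None
    for im in images:
        arr = im.pixels if isinstance(im, StandardImage) else np.asarray(im, float)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError("all images must share one shape")
        rows.append(arr.ravel())
    return np.asarray(rows)


class FittedFeatureClassifier:
    """A fitted estimator bound to the image shape it was trained on."""

    def __init__(self, estimator, image_shape: tuple[int, int], spec: ClassifierSpec):
        self.estimator = estimator
        self.image_shape = image_shape
        self.spec = spec

    def predict_proba(self, images) -> np.ndarray:
        single = isinstance(images, StandardImage) or (
            isinstance(images, np.ndarray) and images.ndim == 2)
        batch = [images] if single else list(images)
        X = _as_matrix(batch)
        if X.shape[1] != int(np.prod(self.image_shape)):
            raise ValueError(
                f"image shape mismatch: model expects {self.image_shape}")
        pos = list(self.estimator.classes_).index(1)
        p = self.estimator.predict_proba(X)[:, pos]
        return float(p[0]) if single else p


def train_classifier(images: Sequence, labels: Sequence,
                     spec: ClassifierSpec) -> FittedFeatureClassifier:
    """Fit one binary feature classifier on flattened pixel vectors."""
    X = _as_matrix(images)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        missing = 1 - int(classes[0])
        raise ValueError(f"training labels contain a single class; class {missing} is absent")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")
    est = spec.make_estimator()
    est.fit(X, y)
    first = images[0]
    shape = first.pixels.shape if isinstance(first, StandardImage) else np.asarray(first).shape
    return FittedFeatureClassifier(est, shape, spec)


def predict_proba(model: FittedFeatureClassifier, image) -> float | np.ndarray:
    """Probability of the abnormal pole (class 1) for an image or batch."""
    return model.predict_proba(image)


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the tie-aware Mann-Whitney probability via midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _auc_p_value(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    n = len(scores)
    method = "exact" if n < 30 and len(np.unique(scores)) == n else "asymptotic"
    return float(stats.mannwhitneyu(pos, neg, alternative="two-sided",
                                    method=method).pvalue)


def compute_metrics(probabilities, labels, threshold: float = 0.5) -> MetricsReport:
    """Threshold metrics and AUC against binary labels.

    With no positive labels recall is undefined and reported as NaN (not 0);
    likewise precision when nothing is predicted positive.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    if np.isfinite(recall) and np.isfinite(precision) and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = float("nan")
    accuracy = (tp + tn) / len(y)
    if 0 < y.sum() < len(y):
        auc = auc_mann_whitney(p, y)
        pval = _auc_p_value(p, y)
    else:
        auc, pval = float("nan"), float("nan")
    return MetricsReport(auc=auc, recall=recall, precision=precision,
                         f1_score=f1, accuracy=accuracy, p_value=pval,
                         threshold=threshold)


def crossvalidate_fourfold(images: Sequence, labels: Sequence,
                           spec: ClassifierSpec, seed: int = 0,
                           n_folds: int = 4,
                           augment: bool = True) -> tuple[MetricsReport, np.ndarray]:
    """Stratified fourfold cross-validation with training-fold augmentation.

    Subjects are partitioned before augmentation; per round, 75% of subjects
    (doubled by horizontal flips when ``augment``) train the classifier and
    the remaining 25% are scored.  Returns the pooled metrics report and the
    per-subject out-of-fold probabilities in input order.
    """
    y = np.asarray(labels, dtype=int)
    if len(images) < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} subjects for {n_folds}-fold CV")
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            "a fold would miss a class: fewer examples of the rarer class than "
            "folds; regenerate with a different stratification seed or more data")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.full(len(images), np.nan)
    per_fold = []
    for k, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        tr_imgs = [images[i] for i in tr]
        tr_y = list(y[tr])
        if augment:
            tr_imgs, tr_y = augment_flip(tr_imgs, tr_y)
        model = train_classifier(tr_imgs, tr_y, spec)
        p = model.predict_proba([images[i] for i in va])
        oof[va] = p
        per_fold.append(compute_metrics(p, y[va]))
    report = compute_metrics(oof, y)
    report.per_fold = per_fold
    return report, oof
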