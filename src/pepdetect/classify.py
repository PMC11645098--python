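"""Bagged-trees classification with repeated stratified cross-validation.

The positive class is "Unpredicted".  Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), accuracy = (TP+TN)/total.  Repeated CV runs
n_repeats independent stratified n_folds partitions; within each
repetition the held-out predictions are pooled into one confusion table,
and the per-repetition metrics are summarized as mean +/- sd.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix
from .synthetic import PREDICTED, UNPREDICTED

logger = logging.getLogger(__name__)

POSITIVE_CLASS = UNPREDICTED
NEGATIVE_CLASS = PREDICTED


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero."""


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int = 100
    max_depth: int | None = None
    n_folds: int = 10
    n_repeats: int = 10
    subject_blocked: bool = False
    seed: int = 0


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_labels(
        cls, y_true: np.ndarray, y_pred: np.ndarray, positive: str = POSITIVE_CLASS
    ) -> "ConfusionCounts":
        t = np.asarray(y_true) == positive
        p = np.asarray(y_pred) == positive
        return cls(
            TP=int(np.sum(t & p)),
            TN=int(np.sum(~t & ~p)),
            FP=int(np.sum(~t & p)),
            FN=int(np.sum(t & ~p)),
        )


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    accuracy: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity/specificity/accuracy; zero denominators are flagged
    (value NaN, name in .undefined) rather than silently 0."""
    undefined = set()
    if counts.TP + counts.FN > 0:
        sens = counts.TP / (counts.TP + counts.FN)
    else:
        sens, undefined = float("nan"), undefined | {"sensitivity"}
    if counts.TN + counts.FP > 0:
        spec = counts.TN / (counts.TN + counts.FP)
    else:
        spec, undefined = float("nan"), undefined | {"specificity"}
    if counts.total > 0:
        acc = (counts.TP + counts.TN) / counts.total
    else:
        acc, undefined = float("nan"), undefined | {"accuracy"}
    return Metrics(sens, spec, acc, frozenset(undefined))


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

@dataclass
class TrainedEnsemble:
    """Bootstrap-aggregated decision trees; ties in the vote are broken
    toward the negative class to favor specificity."""

    model: BaggingClassifier
    config: ClassifierConfig
    positive: str = POSITIVE_CLASS
    negative: str = NEGATIVE_CLASS

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        pos_idx = list(self.model.classes_).index(self.positive)
        proba = self.model.predict_proba(X)[:, pos_idx]
        return np.where(proba > 0.5, self.positive, self.negative)


def train_bagged_trees(
    features: FeatureMatrix | np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
    labels: np.ndarray | None = None,
) -> TrainedEnsemble:
    X, y = _unpack(features, labels)
    classes = sorted(np.unique(y))
    if len(classes) != 2:
        raise ValueError(
            "training requires exactly two classes, got " + repr(classes)
        )
    # positive = the rare/critical class by naming convention
    positive = next(
        (c for c in classes if c in ("Unpredicted", "Unexpected")), classes[-1]
    )
    negative = next(c for c in classes if c != positive)
    model = BaggingClassifier(
        estimator=DecisionTreeClassifier(
            max_depth=config.max_depth, random_state=config.seed
        ),
        n_estimators=config.n_trees,
        bootstrap=True,
        random_state=config.seed,
    )
    model.fit(X, y)
    return TrainedEnsemble(
        model=model, config=config, positive=positive, negative=negative
    )


def _unpack(features, labels):
    if isinstance(features, FeatureMatrix):
        if features.labels is None:
            raise ValueError("feature matrix has no labels")
        return features.X, np.asarray(features.labels, dtype=object)
    return np.asarray(features, dtype=float), np.asarray(labels, dtype=object)


# ---------------------------------------------------------------------------
# Repeated cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    per_repetition: list[Metrics]
    config: ClassifierConfig

    def _vals(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.per_repetition])

    def mean(self, name: str) -> float:
        return float(np.nanmean(self._vals(name)))

    def sd(self, name: str) -> float:
        return float(np.nanstd(self._vals(name), ddof=1))

    def summary(self) -> dict:
        return {
            name: {"mean": self.mean(name), "sd": self.sd(name)}
            for name in ("sensitivity", "specificity", "accuracy")
        }


def repeated_cv(
    features: FeatureMatrix | np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
    labels: np.ndarray | None = None,
    groups: np.ndarray | None = None,
) -> CVResult:
    """n_repeats independent stratified n_folds partitions.

    With subject_blocked=True, folds are stratified over subjects instead of
    epochs (all of a subject's epochs share a fold), using the groups array
    (defaults to the feature matrix's epoch_refs subjects).
    """
    X, y = _unpack(features, labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation requires two classes")
    if counts.min() < config.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify "
            f"{config.n_folds} folds"
        )
    if config.subject_blocked and groups is None:
        if isinstance(features, FeatureMatrix) and features.epoch_refs:
            groups = np.array([ref[0] for ref in features.epoch_refs])
        else:
            raise ValueError("subject_blocked CV requires a groups array")

    per_rep: list[Metrics] = []
    for rep in range(config.n_repeats):
        rep_seed = config.seed + 1000 * rep
        y_pred = np.empty(len(y), dtype=object)
        for train_idx, test_idx in _partitions(y, groups, config, rep_seed):
            fold_cfg = ClassifierConfig(
                n_trees=config.n_trees, max_depth=config.max_depth, seed=rep_seed
            )
            ens = train_bagged_trees(X[train_idx], fold_cfg, labels=y[train_idx])
            y_pred[test_idx] = ens.predict(X[test_idx])
        per_rep.append(compute_metrics(ConfusionCounts.from_labels(y, y_pred)))
    return CVResult(per_repetition=per_rep, config=config)


def _partitions(y, groups, config, seed):
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
    if not config.subject_blocked:
        yield from skf.split(np.zeros(len(y)), y)
        return
    # subject-blocked: stratify subjects by their majority label
    uniq = np.unique(groups)
    maj = np.array(
        [
            max(set(y[groups == g]), key=list(y[groups == g]).count)
            for g in uniq
        ]
    )
    n_splits = min(config.n_folds, len(uniq))
    skf_g = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for tr_g, te_g in skf_g.split(np.zeros(len(uniq)), maj):
        train_mask = np.isin(groups, uniq[tr_g])
        yield np.where(train_mask)[0], np.where(~train_mask)[0]
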