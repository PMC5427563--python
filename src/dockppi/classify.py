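"""Random-forest interaction classifier, ROC analysis and decision rules.

A random-forest ensemble is trained on per-model binding-energy features to
output a single probability that a dimer model represents a biologically
relevant interaction. The operating point is chosen by scanning probability
thresholds for the maximum Matthews correlation coefficient, and a pair-level
decision aggregates per-model probabilities: a receptor-ligand pair is called
interacting if any of its top-n ranked models scores strictly above the
threshold. The default threshold of 0.13 is the MCC-maximizing operating
point reported for this kind of energy-feature classifier; default top_n is
3, the configuration that maximizes pair-level MCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from dockppi.features import FEATURE_COLUMNS
from dockppi.interface_metrics import ClassificationMetrics, ConfusionCounts, classify_metrics

__all__ = [
    "DecisionRule",
    "PairPrediction",
    "RocCurve",
    "InteractionClassifier",
    "train_classifier",
    "cross_validate",
    "roc_curve",
    "select_threshold_max_mcc",
    "aggregate_topn",
    "predict_pairs",
]

DEFAULT_THRESHOLD = 0.13
DEFAULT_TOP_N = 3
DEFAULT_N_TREES = 500
DEFAULT_MIN_LEAF = 10


@dataclass(frozen=True)
class DecisionRule:
    """Pair-level decision: positive iff any top-n model probability > threshold."""

    probability_threshold: float = DEFAULT_THRESHOLD
    top_n: int = DEFAULT_TOP_N

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability_threshold <= 1.0):
            raise ValueError("probability threshold must be in [0, 1]")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass(frozen=True)
class PairPrediction:
    pair_id: str
    probabilities: tuple[float, ...]  # ordered by model rank
    decision: bool
    max_considered_prob: float


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class InteractionClassifier:
    """Probability-scoring wrapper around a random-forest backend."""

    model: RandomForestClassifier
    feature_columns: tuple[str, ...] = field(default=FEATURE_COLUMNS)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(self.feature_columns)].to_numpy(dtype=float)
        return self.model.predict_proba(X)[:, 1]


def _stack(positives: pd.DataFrame, negatives: pd.DataFrame):
    if positives.empty or negatives.empty:
        raise ValueError("both positive and negative examples are required")
    X = np.vstack(
        [
            positives[list(FEATURE_COLUMNS)].to_numpy(dtype=float),
            negatives[list(FEATURE_COLUMNS)].to_numpy(dtype=float),
        ]
    )
    y = np.concatenate([np.ones(len(positives), int), np.zeros(len(negatives), int)])
    return X, y


def train_classifier(
    positives: pd.DataFrame,
    negatives: pd.DataFrame,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    min_samples_leaf: int = DEFAULT_MIN_LEAF,
) -> InteractionClassifier:
    """Fit the random forest on labeled feature tables; deterministic per seed.

    `min_samples_leaf` defaults to 10: vote fractions from fully grown trees
    are too granular to rank pairs well, and a modest leaf-size floor
    smooths the probability estimates.
    """
    X, y = _stack(positives, negatives)
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed,
        min_samples_leaf=min_samples_leaf,
        n_jobs=1,
    )
    rf.fit(X, y)
    return InteractionClassifier(model=rf)


def cross_validate(
    positives: pd.DataFrame,
    negatives: pd.DataFrame,
    k: int = 10,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    min_samples_leaf: int = DEFAULT_MIN_LEAF,
) -> tuple[pd.DataFrame, RocCurve]:
    """Stratified k-fold cross-validation with out-of-fold probabilities.

    Every example is scored exactly once by a model that never saw it.
    Returns a frame with columns `label` and `prob` (original row order:
    positives then negatives) and the pooled out-of-fold ROC curve.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(positives) < k or len(negatives) < k:
        raise ValueError("each class needs at least k examples")
    X, y = _stack(positives, negatives)
    probs = np.full(len(y), np.nan)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=seed,
            min_samples_leaf=min_samples_leaf,
            n_jobs=1,
        )
        rf.fit(X[train_idx], y[train_idx])
        probs[test_idx] = rf.predict_proba(X[test_idx])[:, 1]
    assert not np.isnan(probs).any()
    oof = pd.DataFrame({"label": y, "prob": probs})
    return oof, roc_curve(probs, y)


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC over the threshold sweep of unique scores, with trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_sk_auc(fpr, tpr)))


def select_threshold_max_mcc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, ClassificationMetrics]:
    """The probability threshold maximizing MCC under the strict-> decision.

    Candidate thresholds are the unique score values; a score is called
    positive iff it is strictly greater than the threshold. Ties on MCC
    resolve to the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    candidates = np.unique(scores)
    best: tuple[float, ClassificationMetrics] | None = None
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    for t in candidates:
        pred = scores > t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        m = classify_metrics(
            ConfusionCounts(TP=tp, FP=fp, TN=n_neg - fp, FN=n_pos - tp)
        )
        if best is None or m.MCC > best[1].MCC + 1e-15:
            best = (float(t), m)
    assert best is not None
    return best


def aggregate_topn(per_model_probs: Sequence[float], rule: DecisionRule) -> bool:
    """True iff any of the first min(top_n, len) probabilities is strictly
    greater than the rule's threshold."""
    probs = list(per_model_probs)
    if not probs:
        raise ValueError("empty probability list")
    considered = probs[: rule.top_n]
    return any(p > rule.probability_threshold for p in considered)


def predict_pairs(
    clf: InteractionClassifier, table: pd.DataFrame, rule: DecisionRule
) -> list[PairPrediction]:
    """Score a feature table and apply the top-n decision rule per pair.

    Models within a pair are ordered by `model_rank`.
    """
    table = table.sort_values(["pair_id", "model_rank"], kind="stable")
    probs = clf.predict_proba(table)
    out: list[PairPrediction] = []
    scored = table.assign(_prob=probs)
    for pair_id, group in scored.groupby("pair_id", sort=True):
        p = tuple(float(x) for x in group["_prob"])
        considered = p[: rule.top_n]
        out.append(
            PairPrediction(
                pair_id=str(pair_id),
                probabilities=p,
                decision=aggregate_topn(p, rule),
                max_considered_prob=max(considered),
            )
        )
    return out
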