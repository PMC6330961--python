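"""Boosted-tree cluster classifiers with nested CV and minority up-sampling.

One gradient-boosting model is trained per loop group on one-hot encoded
flanked sequences.  Hyper-parameters (number of trees, weak-learner depth,
learning rate, minimum node size) are chosen by grid search inside a nested
repeated stratified CV: the inner CV scores every grid point on each outer
training partition, the best point is refit on that partition (with
minority classes up-sampled inside the training data only) and evaluated on
the held-out outer fold.  Outer accuracies and confusion tallies are
averaged per repeat and then across repeats; the final model is refit on
all data with the hyper-parameters of highest mean inner accuracy.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.utils.validation import check_is_fitted

from .cv import FoldAssignment, spawn_seed, stratified_folds, upsample_indices
from .encoding import FeatureMatrix, encode_group
from .nullstats import ConfusionTally
from .records import LoopGroup

__all__ = [
    "HyperGrid",
    "UpsampledGradientBoosting",
    "TrainedGroupModel",
    "nested_cv_train",
    "feature_importance",
]

logger = logging.getLogger(__name__)

#: Up-sampling cap: minority classes are replicated up to
#: min(UPSAMPLE_CAP, majority-class size).
UPSAMPLE_CAP = 50


@dataclass(frozen=True)
class HyperGrid:
    """Grid-search space for the boosted-tree hyper-parameters.

    ``max_branches`` is the weak-learner complexity, encoded as maximum tree
    depth.  The defaults are a modest space around the scale at which short
    one-hot sequence features saturate.
    """

    n_trees: tuple[int, ...] = (50, 100, 200, 400)
    max_branches: tuple[int, ...] = (1, 2, 3)
    learning_rate: tuple[float, ...] = (0.1,)
    min_node_size: tuple[int, ...] = (5,)

    def __post_init__(self):
        for name in ("n_trees", "max_branches", "learning_rate", "min_node_size"):
            vals = getattr(self, name)
            if not vals or any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be a nonempty list of positives")

    def points(self) -> list[dict]:
        return [
            {"n_trees": nt, "max_branches": mb, "learning_rate": lr,
             "min_node_size": mn}
            for nt, mb, lr, mn in itertools.product(
                self.n_trees, self.max_branches, self.learning_rate,
                self.min_node_size)
        ]


class UpsampledGradientBoosting(ClassifierMixin, BaseEstimator):
    """Gradient-boosting classifier that up-samples minorities during fit.

    Minority classes in the training data are replicated with replacement up
    to ``min(upsample_cap, majority size)`` before fitting; prediction is the
    probability argmax with ties broken by lexicographic class order.
    """

    def __init__(self, n_trees: int = 100, max_branches: int = 2,
                 learning_rate: float = 0.1, min_node_size: int = 5,
                 upsample_cap: int = UPSAMPLE_CAP, random_state: int = 0):
        self.n_trees = n_trees
        self.max_branches = max_branches
        self.learning_rate = learning_rate
        self.min_node_size = min_node_size
        self.upsample_cap = upsample_cap
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        idx = upsample_indices(y, cap=self.upsample_cap,
                               seed=spawn_seed(self.random_state, 1))
        self.resampled_indices_ = idx
        self.estimator_ = GradientBoostingClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_branches,
            learning_rate=self.learning_rate,
            min_samples_leaf=self.min_node_size,
            random_state=spawn_seed(self.random_state, 2),
        ).fit(X[idx], y[idx])
        self.classes_ = self.estimator_.classes_  # sorted lexicographically
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(np.asarray(X))

    def predict(self, X):
        proba = self.predict_proba(X)
        # argmax returns the first (lexicographically smallest) class on ties
        return self.classes_[np.argmax(proba, axis=1)]

    @property
    def feature_importances_(self):
        check_is_fitted(self, "estimator_")
        return self.estimator_.feature_importances_


def feature_importance(model, feature_names: Sequence[str]) -> dict[str, float]:
    """Node-size-weighted impurity-reduction importances scaled to max 100."""
    raw = np.asarray(model.feature_importances_, dtype=np.float64)
    peak = raw.max()
    if peak > 0:
        raw = raw * (100.0 / peak)
        raw[np.argmax(raw)] = 100.0  # guard the scaled maximum from fp error
    return dict(zip(feature_names, raw))


@dataclass
class TrainedGroupModel:
    """Final fitted model for one loop group plus its CV bookkeeping."""

    loop_type: str
    loop_length: int
    flank_width: int
    best_params: dict
    model: UpsampledGradientBoosting
    feature_names: list[str]
    importance: dict[str, float]
    outer_accuracy_mean: float
    outer_accuracy_sd: float
    per_repeat_accuracy: np.ndarray
    inner_scores: dict[tuple, float] = field(default_factory=dict)
    fold_details: list[dict] = field(default_factory=list)

    def top_features(self, k: int = 10) -> list[tuple[str, float]]:
        return sorted(self.importance.items(), key=lambda kv: -kv[1])[:k]

    def predict(self, records, encoder=None):
        from .encoding import OneHotCdrEncoder

        enc = encoder or OneHotCdrEncoder(self.flank_width).fit(records)
        X = enc.transform(records)
        proba = self.model.predict_proba(X)
        return self.model.classes_[np.argmax(proba, axis=1)], proba


def _inner_cv_score(X, y, params, n_folds, n_repeats, cap, seed) -> float:
    """Mean held-out accuracy of one grid point under inner repeated CV."""
    inner = stratified_folds(y, n_folds=n_folds, n_repeats=n_repeats, seed=seed)
    accs = []
    for rep in range(n_repeats):
        for k, (tr, te) in enumerate(inner.split(rep)):
            clf = UpsampledGradientBoosting(
                upsample_cap=cap, random_state=spawn_seed(seed, rep, k),
                **params,
            ).fit(X[tr], y[tr])
            accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def nested_cv_train(
    group: LoopGroup,
    grid: Optional[HyperGrid] = None,
    folds: Optional[FoldAssignment] = None,
    flank_width: int = 10,
    inner_folds: int = 10,
    inner_repeats: int = 3,
    upsample_cap: int = UPSAMPLE_CAP,
    seed: int = 0,
    features: Optional[FeatureMatrix] = None,
) -> tuple[TrainedGroupModel, ConfusionTally]:
    """Nested-CV training and evaluation of one loop group.

    Up-sampling happens inside each training partition only; held-out folds
    are never resampled (``fold_details`` records the index sets so the
    guarantee is auditable).  Returns the final model — refit on all data
    with the best grid point — and the outer confusion tally averaged over
    repeats.
    """
    grid = grid or HyperGrid()
    fm = features or encode_group(group, flank_width)
    X = fm.values.astype(np.float64)
    y = np.asarray(fm.labels)
    all_classes = sorted(set(fm.labels))
    if folds is None:
        folds = stratified_folds(y, n_folds=10, n_repeats=3,
                                 seed=spawn_seed(seed, 10))

    points = grid.points()
    inner_totals: dict[tuple, list[float]] = {
        tuple(sorted(p.items())): [] for p in points
    }
    fold_details: list[dict] = []
    repeat_tallies: list[ConfusionTally] = []
    accuracies = []

    for rep in range(folds.n_repeats):
        true_all, pred_all = [], []
        for k, (train_idx, test_idx) in enumerate(folds.split(rep)):
            missing = set(all_classes) - set(y[train_idx])
            if missing:
                raise ValueError(
                    f"class(es) {sorted(missing)} absent from the training "
                    f"partition of repeat {rep}, fold {k}"
                )
            best_p, best_score = None, -np.inf
            for p in points:
                score = _inner_cv_score(
                    X[train_idx], y[train_idx], p, inner_folds, inner_repeats,
                    upsample_cap, spawn_seed(seed, 20, rep, k),
                ) if len(points) > 1 else 1.0
                inner_totals[tuple(sorted(p.items()))].append(score)
                if score > best_score:
                    best_p, best_score = p, score
            clf = UpsampledGradientBoosting(
                upsample_cap=upsample_cap,
                random_state=spawn_seed(seed, 30, rep, k), **best_p,
            ).fit(X[train_idx], y[train_idx])
            pred = clf.predict(X[test_idx])
            true_all.extend(y[test_idx])
            pred_all.extend(pred)
            fold_details.append({
                "repeat": rep, "fold": k, "params": best_p,
                "train_idx": train_idx, "test_idx": test_idx,
                "resampled_idx": train_idx[clf.resampled_indices_],
            })
        tally = ConfusionTally.from_predictions(
            true_all, pred_all, labels=all_classes, loop_key=group.key
        )
        repeat_tallies.append(tally)
        accuracies.append(tally.accuracy)

    inner_scores = {k: float(np.mean(v)) for k, v in inner_totals.items()}
    best_key = max(sorted(inner_scores), key=lambda k: inner_scores[k])
    best_params = dict(best_key)
    logger.info("%s: best hyper-parameters %s", group.key, best_params)

    final = UpsampledGradientBoosting(
        upsample_cap=upsample_cap, random_state=spawn_seed(seed, 40),
        **best_params,
    ).fit(X, y)
    acc = np.array(accuracies)
    model = TrainedGroupModel(
        loop_type=group.loop_type,
        loop_length=group.loop_length,
        flank_width=flank_width,
        best_params=best_params,
        model=final,
        feature_names=fm.feature_names,
        importance=feature_importance(final, fm.feature_names),
        outer_accuracy_mean=float(acc.mean()),
        outer_accuracy_sd=float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
        per_repeat_accuracy=acc,
        inner_scores=inner_scores,
        fold_details=fold_details,
    )
    return model, ConfusionTally.average(repeat_tallies)
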