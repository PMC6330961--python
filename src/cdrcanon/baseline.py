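"""The blindBLAST baseline: nearest-template cluster inheritance.

RosettaAntibody picks non-H3 CDR templates by PAM30 sequence similarity
against all loops of the same type and length, without looking at cluster
labels; the query implicitly inherits the cluster of its top-scoring
template.  Here that strategy is an estimator: :meth:`fit` stores the
template library, :meth:`predict` runs exhaustive Smith-Waterman scoring
and returns the top template's cluster, ties broken by lexicographically
smallest template id so the result is independent of template order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .alignment import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    align_score,
    load_pam30,
    pairwise_scores,
)
from .cv import FoldAssignment
from .nullstats import ConfusionTally
from .records import CdrRecord, LoopGroup

__all__ = [
    "TemplateHit",
    "BlindBlastClassifier",
    "blindblast_classify",
    "cross_validate_baseline",
]


@dataclass(frozen=True)
class TemplateHit:
    query_id: str
    template_id: str
    score: float
    template_cluster: str


def _seq_of(record: CdrRecord, flanked: bool) -> str:
    return record.flanked_seq if flanked else record.loop_seq


class BlindBlastClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-template cluster classifier under local-alignment scoring.

    Parameters
    ----------
    flanked : bool, default True
        Score the loop plus its framework flanks (as the template database
        used for grafting does) rather than the loop alone.
    matrix : ndarray of shape (20, 20), optional
        Substitution matrix in alphabetical residue order; PAM30 when None.
    gap_open, gap_extend : int
        Affine gap costs; a length-k gap costs ``gap_open + k*gap_extend``.
    """

    def __init__(self, flanked: bool = True, matrix: Optional[np.ndarray] = None,
                 gap_open: int = DEFAULT_GAP_OPEN,
                 gap_extend: int = DEFAULT_GAP_EXTEND):
        self.flanked = flanked
        self.matrix = matrix
        self.gap_open = gap_open
        self.gap_extend = gap_extend

    def fit(self, X: Sequence[CdrRecord], y=None):
        """Store the template library (labels default to record clusters)."""
        templates = list(X)
        if not templates:
            raise ValueError("template list is empty")
        labels = [r.cluster_label for r in templates] if y is None else list(y)
        lengths = {r.loop_length for r in templates}
        if len(lengths) != 1:
            raise ValueError(f"templates mix loop lengths {sorted(lengths)}")
        self.templates_ = templates
        self.template_labels_ = labels
        self.classes_ = np.array(sorted(set(labels)))
        return self

    def _score_against_templates(self, query: CdrRecord) -> np.ndarray:
        mat = load_pam30() if self.matrix is None else self.matrix
        qseq = _seq_of(query, self.flanked)
        return np.array([
            align_score(qseq, _seq_of(t, self.flanked), mat,
                        self.gap_open, self.gap_extend)
            for t in self.templates_
        ], dtype=np.float64)

    def predict_hits(self, X: Sequence[CdrRecord]) -> list[TemplateHit]:
        """Best template per query; a template sharing the query's id is
        excluded (a record never templates itself)."""
        hits = []
        for query in X:
            scores = self._score_against_templates(query)
            candidates = [
                (t.record_id, scores[i], self.template_labels_[i])
                for i, t in enumerate(self.templates_)
                if t.record_id != query.record_id
            ]
            if not candidates:
                raise ValueError(f"no templates available for {query.record_id}")
            best = max(s for _, s, _ in candidates)
            tid, score, cluster = min(
                (c for c in candidates if c[1] == best), key=lambda c: c[0]
            )
            hits.append(TemplateHit(query.record_id, tid, float(score), cluster))
        return hits

    def predict(self, X: Sequence[CdrRecord]) -> np.ndarray:
        return np.array([h.template_cluster for h in self.predict_hits(X)])


def blindblast_classify(
    query: CdrRecord, templates: Sequence[CdrRecord], **kwargs
) -> tuple[str, TemplateHit]:
    """Classify one query against a template list; see the class docs."""
    clf = BlindBlastClassifier(**kwargs).fit(templates)
    hit = clf.predict_hits([query])[0]
    return hit.template_cluster, hit


def cross_validate_baseline(
    group: LoopGroup,
    folds: FoldAssignment,
    flanked: bool = True,
    matrix: Optional[np.ndarray] = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> tuple[ConfusionTally, np.ndarray]:
    """Repeated-CV evaluation of the baseline on one loop group.

    Within each fold, every held-out query is classified against all
    remaining records as templates.  Per-repeat confusion matrices are
    averaged into one tally; per-repeat accuracies are returned alongside.
    The full pairwise score matrix is computed once and reused across folds.
    """
    records = group.records
    labels = np.array(group.labels)
    ids = np.array([r.record_id for r in records])
    all_classes = sorted(set(group.labels))
    seqs = [_seq_of(r, flanked) for r in records]
    scores = pairwise_scores(seqs, matrix, gap_open, gap_extend)

    repeat_tallies = []
    accuracies = []
    for rep in range(folds.n_repeats):
        true_all, pred_all = [], []
        for train_idx, test_idx in folds.split(rep):
            if train_idx.size == 0:
                raise ValueError("a fold has an empty template pool")
            # order templates by id once so score ties resolve lexicographically
            order = train_idx[np.argsort(ids[train_idx])]
            sub = scores[np.ix_(test_idx, order)]
            best = order[np.argmax(sub, axis=1)]
            true_all.extend(labels[test_idx])
            pred_all.extend(labels[best])
        tally = ConfusionTally.from_predictions(
            true_all, pred_all, labels=all_classes, loop_key=group.key
        )
        repeat_tallies.append(tally)
        accuracies.append(tally.accuracy)
    return ConfusionTally.average(repeat_tallies), np.array(accuracies)
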