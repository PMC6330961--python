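"""Random-assignment null model and misclassification statistics.

The null model asks: if every query were assigned a cluster at random, in
proportion to the naturally occurring cluster frequencies, how many
X -> Y misclassifications would we see?  Under that model the expected
error count is ``E[eps^{X->Y}] = n_X * P_Y``, a chi-square goodness-of-fit
statistic over the off-diagonal cells measures whether an observed
confusion tally differs from random overall, and a per-cell empirical
p-value from simulated random assignments classifies each misclassification
as better than, like, or worse than random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionTally",
    "NullDistribution",
    "Category",
    "expected_error",
    "chi_square_fit",
    "random_assignment_sim",
    "empirical_p",
    "categorize",
    "compare_methods",
]

logger = logging.getLogger(__name__)


class Category(str, Enum):
    BETTER_THAN_RANDOM = "better_than_random"
    RANDOM_LIKE = "random_like"
    WORSE_THAN_RANDOM = "worse_than_random"


@dataclass
class ConfusionTally:
    """True-vs-predicted counts for one loop group, averaged over CV repeats.

    ``counts`` is a square DataFrame, rows = true cluster, columns =
    predicted cluster, identically ordered.  Row sums equal the per-cluster
    query counts (conservation).
    """

    counts: pd.DataFrame
    n_repeats: int = 1
    loop_key: str = ""

    @classmethod
    def from_predictions(cls, true_labels, predicted_labels, labels=None,
                         loop_key: str = "") -> "ConfusionTally":
        labels = (sorted(set(true_labels) | set(predicted_labels))
                  if labels is None else list(labels))
        counts = pd.DataFrame(0.0, index=labels, columns=labels)
        for t, p in zip(true_labels, predicted_labels):
            counts.loc[t, p] += 1.0
        return cls(counts=counts, n_repeats=1, loop_key=loop_key)

    @classmethod
    def average(cls, tallies: Sequence["ConfusionTally"]) -> "ConfusionTally":
        """Average per-repeat tallies into one tally."""
        labels = sorted(set().union(*(t.counts.index for t in tallies)))
        total = pd.DataFrame(0.0, index=labels, columns=labels)
        for t in tallies:
            total = total.add(
                t.counts.reindex(index=labels, columns=labels, fill_value=0.0),
                fill_value=0.0,
            )
        return cls(counts=total / len(tallies), n_repeats=len(tallies),
                   loop_key=tallies[0].loop_key)

    @property
    def labels(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_total(self) -> float:
        return float(self.counts.to_numpy().sum())

    @property
    def n_errors(self) -> float:
        c = self.counts.to_numpy()
        return float(c.sum() - np.trace(c))

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts.to_numpy()) / self.n_total)

    def class_sizes(self) -> dict[str, float]:
        return self.counts.sum(axis=1).to_dict()

    def off_diagonal(self) -> dict[tuple[str, str], float]:
        out = {}
        for x in self.labels:
            for y in self.labels:
                if x != y:
                    out[(x, y)] = float(self.counts.loc[x, y])
        return out

    def accuracy_excluding(self, label: str) -> float:
        """Accuracy over queries whose true label is not ``label``."""
        keep = [l for l in self.labels if l != label]
        sub = self.counts.loc[keep]
        total = float(sub.to_numpy().sum())
        if total == 0:
            raise ValueError(f"all queries have true label {label!r}")
        correct = sum(float(sub.loc[l, l]) for l in keep if l in sub.columns)
        return correct / total


def expected_error(n_x: float, p_y: float) -> float:
    """Expected X -> Y error count under random assignment: n_X * P_Y."""
    if not 0.0 <= p_y <= 1.0:
        raise ValueError("p_y must be a fraction in [0, 1]")
    return n_x * p_y


def chi_square_fit(tally: ConfusionTally) -> tuple[float, int, float]:
    """Chi-square goodness of fit of a tally against the random null.

    Sums ``(obs - exp)^2 / exp`` over off-diagonal cells, with expectation
    ``n_X * P_Y`` from the tally's own class sizes.  Degrees of freedom are
    taken as the number of clusters (the convention used when this test was
    introduced for confusion tallies; the textbook cells-minus-one choice
    differs — see the methods note).  Cells with zero expected count are
    excluded with a warning.  A small statistic means the observed errors
    look random.
    """
    sizes = tally.class_sizes()
    total = sum(sizes.values())
    chi2 = 0.0
    for (x, y), obs in tally.off_diagonal().items():
        exp = expected_error(sizes[x], sizes[y] / total)
        if exp == 0.0:
            logger.warning(
                "%s: zero expected count for %s->%s, cell excluded",
                tally.loop_key, x, y,
            )
            continue
        chi2 += (obs - exp) ** 2 / exp
    df = len(tally.labels)
    p_value = float(stats.chi2.sf(chi2, df))
    return chi2, df, p_value


@dataclass
class NullDistribution:
    """Simulated random-assignment error counts for one loop group.

    ``simulated[(X, Y)]`` holds the X -> Y error count of every iteration;
    ``expected[(X, Y)]`` the analytic expectation ``n_X * P_Y``.
    """

    cluster_sizes: dict[str, int]
    n_iter: int
    seed: int
    simulated: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    expected: dict[tuple[str, str], float] = field(default_factory=dict)

    def p_value(self, x: str, y: str, observed: float) -> float:
        return empirical_p(observed, self.simulated[(x, y)])

    def accuracies(self) -> np.ndarray:
        """Overall assignment accuracy of each iteration."""
        total = sum(self.cluster_sizes.values())
        errors = np.zeros(self.n_iter)
        for counts in self.simulated.values():
            errors += counts
        return 1.0 - errors / total


def random_assignment_sim(
    cluster_sizes: Mapping[str, int], n_iter: int = 10_000, seed: int = 0
) -> NullDistribution:
    """Simulate random cluster assignment in proportion to class frequency.

    Each iteration independently assigns every query a predicted label drawn
    from the empirical class-frequency distribution (the query's own class
    included, so the analytic expectation ``n_X * P_Y`` holds exactly);
    only off-diagonal (error) counts are recorded.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    labels = sorted(cluster_sizes)
    sizes = np.array([cluster_sizes[l] for l in labels], dtype=np.int64)
    total = int(sizes.sum())
    if total < 2:
        raise ValueError("need at least two queries to simulate")
    p = sizes / total
    rng = np.random.default_rng(seed)
    null = NullDistribution(cluster_sizes=dict(cluster_sizes), n_iter=n_iter,
                            seed=seed)
    for i, x in enumerate(labels):
        # predictions for the n_X queries of true class X are iid categorical,
        # so their per-class counts are one multinomial draw per iteration
        draws = rng.multinomial(sizes[i], p, size=n_iter)
        for j, y in enumerate(labels):
            if x == y:
                continue
            null.simulated[(x, y)] = draws[:, j].astype(np.float64)
            null.expected[(x, y)] = expected_error(int(sizes[i]), float(p[j]))
    return null


def empirical_p(eps_obs: float, simulated: np.ndarray) -> float:
    """Fraction of simulated error counts at or below the observed count.

    Large p means the observed method errs at least as much as random for
    this misclassification; small p means it errs less.
    """
    simulated = np.asarray(simulated)
    if simulated.size == 0:
        raise ValueError("simulated distribution is empty")
    return float(np.count_nonzero(eps_obs >= simulated) / simulated.size)


def categorize(p: float) -> Category:
    """Two-tailed categorization at the 0.05 level (0.025 in each tail)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p <= 0.025:
        return Category.BETTER_THAN_RANDOM
    if p >= 0.975:
        return Category.WORSE_THAN_RANDOM
    return Category.RANDOM_LIKE


def compare_methods(
    tally_a: ConfusionTally, tally_b: ConfusionTally, min_diff: float = 3.0
) -> list[tuple[str, str, float]]:
    """Per-misclassification error-count deltas (a minus b).

    Returns ``(true, predicted, delta)`` for every off-diagonal cell with
    ``|delta| >= min_diff``, sorted by decreasing ``|delta|``.
    """
    if set(tally_a.labels) != set(tally_b.labels):
        raise ValueError("tallies cover different cluster label sets")
    deltas = []
    b = tally_b.off_diagonal()
    for (x, y), a_count in tally_a.off_diagonal().items():
        d = a_count - b[(x, y)]
        if abs(d) >= min_diff:
            deltas.append((x, y, d))
    deltas.sort(key=lambda t: -abs(t[2]))
    return deltas
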