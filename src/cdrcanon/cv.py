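"""Fold assignment and minority up-sampling shared by both classifiers.

Both the template-similarity baseline and the boosted-tree models are
evaluated under the same repeated stratified k-fold scheme (default 3
repeats of 10 folds) so their confusion tallies are directly comparable.
Up-sampling replicates minority-class training samples with replacement up
to ``min(cap, majority size)`` and is applied only inside training
partitions, never to held-out data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = ["FoldAssignment", "stratified_folds", "upsample_indices", "spawn_seed"]


def spawn_seed(master_seed: int, *path: int) -> int:
    """Derive a sub-seed below 2**31 from a master seed and a path of ints.

    Every RNG in the package draws its seed through this single scheme so a
    run is reproducible from one master seed.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(path))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class FoldAssignment:
    """Stratified fold indices for every repeat of a CV scheme."""

    n_repeats: int
    n_folds: int
    seed: int
    #: fold index per sample, one array of length n_samples per repeat
    folds: list[np.ndarray] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.folds[0])

    def split(self, repeat: int):
        """Yield (train_idx, test_idx) for each fold of one repeat."""
        assignment = self.folds[repeat]
        for f in range(self.n_folds):
            test = np.flatnonzero(assignment == f)
            train = np.flatnonzero(assignment != f)
            yield train, test


def stratified_folds(
    labels, n_folds: int = 10, n_repeats: int = 3, seed: int = 0
) -> FoldAssignment:
    """Assign samples to stratified folds, independently per repeat.

    Per-fold class counts differ from exact proportionality by at most one
    sample per class; classes smaller than ``n_folds`` are spread as evenly
    as possible (one member per fold until exhausted).
    """
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(labels):
        raise ValueError("n_folds exceeds the number of samples")
    assignment = FoldAssignment(n_repeats=n_repeats, n_folds=n_folds, seed=seed)
    import warnings

    for rep in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True,
            random_state=spawn_seed(seed, 0, rep),
        )
        folds = np.empty(len(labels), dtype=np.int64)
        with warnings.catch_warnings():
            # classes smaller than n_folds are expected in sparse clusters
            warnings.simplefilter("ignore", UserWarning)
            for f, (_, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
                folds[test] = f
        assignment.folds.append(folds)
    return assignment


def upsample_indices(labels, cap: int = 50, seed: int = 0) -> np.ndarray:
    """Indices of a training set after minority up-sampling.

    The target count is ``T = min(cap, size of the largest class)``.  Every
    class below T gains samples drawn with replacement from its own members
    until it reaches T; classes at or above T are untouched.  The returned
    index multiset always contains each original index at least once.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("no samples to up-sample")
    counts = Counter(labels.tolist())
    target = min(cap, max(counts.values()))
    rng = np.random.default_rng(seed)
    extra = []
    for cls, n in sorted(counts.items()):
        if n < target:
            members = np.flatnonzero(labels == cls)
            extra.append(rng.choice(members, size=target - n, replace=True))
    if extra:
        return np.concatenate([np.arange(labels.size)] + extra)
    return np.arange(labels.size)
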