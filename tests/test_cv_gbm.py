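"""Fold stratification, minority up-sampling, and the nested-CV boosted
classifier, including the leakage guard and importance oracles."""

import numpy as np
import pytest

from cdrcanon import (
    HyperGrid,
    LoopGroup,
    UpsampledGradientBoosting,
    encode_group,
    feature_importance,
    nested_cv_train,
    stratified_folds,
    upsample_indices,
)
from cdrcanon.records import CdrRecord

from conftest import make_record
from _oracles import stump_gini_reductions


class TestStratifiedFolds:
    def test_balanced_two_class_split(self):
        labels = ["A"] * 50 + ["B"] * 50
        folds = stratified_folds(labels, n_folds=10, n_repeats=1, seed=0)
        labels = np.array(labels)
        for f in range(10):
            fold_labels = labels[folds.folds[0] == f]
            assert (fold_labels == "A").sum() == 5
            assert (fold_labels == "B").sum() == 5

    def test_tiny_class_spread_across_folds(self):
        labels = np.array(["A"] * 97 + ["B"] * 3)
        folds = stratified_folds(labels, n_folds=10, n_repeats=1, seed=1)
        b_folds = folds.folds[0][labels == "B"]
        assert len(set(b_folds.tolist())) == 3  # one member per fold

    def test_same_seed_reproduces_different_seed_differs(self):
        labels = ["A"] * 60 + ["B"] * 40
        f1 = stratified_folds(labels, 10, 2, seed=5)
        f2 = stratified_folds(labels, 10, 2, seed=5)
        f3 = stratified_folds(labels, 10, 2, seed=6)
        for a, b in zip(f1.folds, f2.folds):
            assert np.array_equal(a, b)
        assert any(not np.array_equal(a, b)
                   for a, b in zip(f1.folds, f3.folds))

    def test_folds_partition_the_samples(self):
        labels = ["A"] * 33 + ["B"] * 17
        folds = stratified_folds(labels, n_folds=5, n_repeats=3, seed=2)
        for rep in range(3):
            seen = np.concatenate(
                [test for _, test in folds.split(rep)])
            assert sorted(seen.tolist()) == list(range(50))

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(["A", "B"], n_folds=1, n_repeats=1, seed=0)


class TestUpsample:
    def test_minority_capped_at_50(self):
        labels = np.array(["A"] * 155 + ["B"] * 8)
        idx = upsample_indices(labels, cap=50, seed=0)
        resampled = labels[idx]
        assert (resampled == "A").sum() == 155
        assert (resampled == "B").sum() == 50

    def test_cap_truncates_to_majority_size(self):
        labels = np.array(["A"] * 42 + ["B"] * 5)
        resampled = labels[upsample_indices(labels, cap=50, seed=0)]
        assert (resampled == "A").sum() == 42
        assert (resampled == "B").sum() == 42

    def test_no_minority_untouched(self):
        labels = np.array(["A"] * 50 + ["B"] * 50)
        idx = upsample_indices(labels, cap=50, seed=0)
        assert np.array_equal(idx, np.arange(100))

    def test_every_original_sample_retained(self):
        labels = np.array(["A"] * 30 + ["B"] * 4 + ["C"] * 2)
        idx = upsample_indices(labels, cap=50, seed=3)
        assert set(idx.tolist()) == set(range(36))
        # added samples only come from minority classes
        extra = idx[36:]
        assert all(labels[i] in ("B", "C") for i in extra)


def separable_group(n_a=40, n_b=20, n_c=12, seed=0):
    """Each cluster a distinct deterministic 3-residue motif."""
    rng = np.random.default_rng(seed)
    from cdrcanon.records import AMINO_ACIDS

    def rec(rid, cluster, sig):
        seq = list(rng.choice(list(AMINO_ACIDS), size=8))
        seq[1], seq[4], seq[6] = sig
        return make_record(rid=rid, loop_seq="".join(seq), cluster=cluster,
                           flank_up="", flank_down="")

    recs = [rec(f"a{i}", "L2-8-1", "GSD") for i in range(n_a)]
    recs += [rec(f"b{i}", "L2-8-2", "YNT") for i in range(n_b)]
    recs += [rec(f"c{i}", "L2-8-3", "WKE") for i in range(n_c)]
    return LoopGroup("L2", 8, recs)


SMALL_GRID = HyperGrid(n_trees=(30,), max_branches=(2,))


class TestNestedCV:
    def test_separable_group_perfect_outer_accuracy(self):
        g = separable_group()
        model, tally = nested_cv_train(
            g, grid=SMALL_GRID, flank_width=0, inner_folds=3,
            inner_repeats=1, seed=0,
            folds=stratified_folds(g.labels, 5, 2, seed=1))
        assert model.outer_accuracy_mean == 1.0
        assert tally.n_errors == 0

    def test_confusion_conservation(self):
        g = separable_group(seed=5)
        folds = stratified_folds(g.labels, 4, 2, seed=2)
        model, tally = nested_cv_train(
            g, grid=SMALL_GRID, flank_width=0, inner_folds=3,
            inner_repeats=1, folds=folds, seed=1)
        n = len(g)
        assert tally.n_total == pytest.approx(n)
        assert tally.n_errors == pytest.approx(
            (1 - model.outer_accuracy_mean) * n)

    def test_upsampling_never_touches_held_out_folds(self):
        g = separable_group(n_a=40, n_b=6, n_c=5, seed=3)
        folds = stratified_folds(g.labels, 4, 1, seed=4)
        model, _ = nested_cv_train(
            g, grid=SMALL_GRID, flank_width=0, inner_folds=3,
            inner_repeats=1, folds=folds, seed=2)
        assert model.fold_details
        for detail in model.fold_details:
            resampled = set(detail["resampled_idx"].tolist())
            held_out = set(detail["test_idx"].tolist())
            assert resampled.isdisjoint(held_out)
            assert resampled <= set(detail["train_idx"].tolist())

    def test_seeded_run_bit_reproducible(self):
        g = separable_group(seed=7)
        kwargs = dict(grid=SMALL_GRID, flank_width=0, inner_folds=3,
                      inner_repeats=1, seed=9,
                      folds=stratified_folds(g.labels, 4, 2, seed=8))
        m1, t1 = nested_cv_train(g, **kwargs)
        m2, t2 = nested_cv_train(g, **kwargs)
        assert t1.counts.equals(t2.counts)
        assert m1.best_params == m2.best_params
        assert m1.importance == m2.importance

    def test_class_absent_from_training_partition_raises(self):
        # 2 folds and a singleton class: the singleton's fold lacks it in
        # the other fold's training partition is fine, but the fold holding
        # it leaves training without the class
        g = separable_group(n_a=10, n_b=10, n_c=1, seed=1)
        folds = stratified_folds(g.labels, 2, 1, seed=0)
        with pytest.raises(ValueError, match="L2-8-3"):
            nested_cv_train(g, grid=SMALL_GRID, flank_width=0,
                            inner_folds=2, inner_repeats=1, folds=folds,
                            seed=0)


class TestPredictContract:
    def test_probabilities_sum_to_one(self, inseparable_group):
        fm = encode_group(inseparable_group, flank_width=2)
        clf = UpsampledGradientBoosting(n_trees=20, random_state=0).fit(
            fm.values.astype(float), np.array(fm.labels))
        proba = clf.predict_proba(fm.values.astype(float))
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_training_record_of_pure_motif_class_confident(self):
        g = separable_group()
        fm = encode_group(g, flank_width=0)
        clf = UpsampledGradientBoosting(n_trees=50, random_state=0).fit(
            fm.values.astype(float), np.array(fm.labels))
        proba = clf.predict_proba(fm.values[:1].astype(float))[0]
        k = list(clf.classes_).index("L2-8-1")
        assert proba[k] > 0.5
        assert clf.predict(fm.values[:1].astype(float))[0] == "L2-8-1"

    def test_prediction_invariant_to_consistent_column_permutation(self):
        g = separable_group(seed=11)
        fm = encode_group(g, flank_width=0)
        X = fm.values.astype(float)
        y = np.array(fm.labels)
        clf = UpsampledGradientBoosting(n_trees=30, random_state=3).fit(X, y)
        rng = np.random.default_rng(12)
        perm = rng.permutation(X.shape[1])
        clf_p = UpsampledGradientBoosting(n_trees=30, random_state=3).fit(
            X[:, perm], y)
        assert np.array_equal(clf.predict(X), clf_p.predict(X[:, perm]))


class TestFeatureImportance:
    def test_marker_feature_dominates(self, cis_group):
        fm = encode_group(cis_group, flank_width=10)
        clf = UpsampledGradientBoosting(n_trees=40, random_state=0).fit(
            fm.values.astype(float), np.array(fm.labels))
        imp = feature_importance(clf, fm.feature_names)
        ranked = sorted(imp.items(), key=lambda kv: -kv[1])
        assert ranked[0][0] == "7:P"
        assert ranked[0][1] == 100.0

    def test_unused_feature_importance_zero(self):
        g = separable_group()
        fm = encode_group(g, flank_width=0)
        clf = UpsampledGradientBoosting(n_trees=30, random_state=0).fit(
            fm.values.astype(float), np.array(fm.labels))
        imp = feature_importance(clf, fm.feature_names)
        never_present = [name for name, col in
                        zip(fm.feature_names, fm.values.T) if col.sum() == 0]
        assert never_present
        assert all(imp[n] == 0.0 for n in never_present)

    def test_depth1_importance_mass_matches_gini_oracle(self):
        # 10-sample fixture: feature 0 separates perfectly, feature 1 is
        # noise; an independent Gini stump computation must agree on where
        # the importance mass lands
        X = np.array([[1, 1], [1, 0], [1, 1], [1, 0], [1, 1],
                      [0, 0], [0, 1], [0, 0], [0, 1], [0, 0]], dtype=float)
        y = np.array(["A"] * 5 + ["B"] * 5)
        reductions = stump_gini_reductions(X.tolist(), y.tolist())
        assert reductions[0] > reductions[1]
        clf = UpsampledGradientBoosting(
            n_trees=10, max_branches=1, random_state=0).fit(X, y)
        imp = feature_importance(clf, ["f0", "f1"])
        assert imp["f0"] == 100.0
        assert imp["f1"] == 0.0
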