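# cdrcanon

Canonical-cluster assignment for antibody non-H3 CDR loops.

Antibody homology modeling pipelines choose structural templates for the
non-H3 complementarity-determining regions (H1, H2, L1, L2, L3) by sequence
similarity.  Loops of the same type and length fall into a small number of
canonical structural clusters (e.g. `H2-10-1`, `L3-9-cis7-1`), and picking a
template from the wrong cluster means grafting a backbone with the wrong
conformation.  `cdrcanon` implements and compares two cluster-assignment
strategies on cluster-annotated CDR tables:

- **blindBLAST** — the implicit strategy used by similarity-based template
  selection: exhaustive Smith–Waterman scoring under PAM30 (affine gaps,
  open 9 / extend 1) against all same-type, same-length loops; the query
  inherits the cluster of the top-scoring template.
- **Gradient-boosted classifiers** — one multiclass boosted-tree model per
  (loop type, length) group on one-hot encoded sequences (loop plus 10
  flanking residues per side, so a length-10 loop is a 30×20 binary window),
  trained under nested repeated stratified cross-validation with
  hyper-parameter grid search in the inner loop and minority up-sampling to
  `min(50, majority size)` inside training partitions only.

Around the classifiers sit the statistics used to interpret them:

- a **random-assignment null model**: predicted labels drawn in proportion
  to the empirical cluster frequencies, so the expected X→Y error count is
  `E[ε^{X→Y}] = n_X · P_Y`; a χ² goodness-of-fit statistic over off-diagonal
  confusion cells, and per-misclassification empirical p-values
  `p = #{ε_random ≤ ε_obs} / n_iter` from 10,000 simulated assignments,
  categorized two-tailed at the 0.05 level (better / like / worse than
  random);
- **dihedral-angle cluster geometry**: the per-loop distance
  `D(i,j) = Σ_r 2(1−cos Δφ_r) + 2(1−cos Δψ_r)`, medoid cluster exemplars,
  cluster radii, and structural-neighbor counts at 1/15 of the radius,
  used to show that queries far from their exemplar are the ones sequence
  methods misclassify;
- **Gini-style feature importances** scaled to \[0, 100\], which recover
  known sequence motifs such as the cis-proline marker at loop position 7
  of `L3-9-cis7-*` clusters;
- a **synthetic data generator** producing cluster-annotated loop groups
  with controllable motif strength, class imbalance and angular dispersion,
  so the whole pipeline is testable without any structure database.

## Worked example

Generate the cis-proline preset (a cluster defined solely by proline at
loop position 7) and compare the two methods on identical folds:

```python
from cdrcanon import (preset_scenarios, generate_group, stratified_folds,
                      cross_validate_baseline, nested_cv_train, HyperGrid)

group = generate_group(preset_scenarios(seed=17)["CIS_MARKER"])
folds = stratified_folds(group.labels, n_folds=5, n_repeats=2, seed=7)

blast_tally, blast_acc = cross_validate_baseline(group, folds)
model, gbm_tally = nested_cv_train(
    group, grid=HyperGrid(n_trees=(50, 100), max_branches=(1, 2)),
    folds=folds, inner_folds=3, inner_repeats=1, seed=8)

print(f"blindBLAST accuracy: {blast_acc.mean():.3f}")
print(f"GBM accuracy:        {model.outer_accuracy_mean:.3f}")
print("top features:", model.top_features(3))
```

prints

```
blindBLAST accuracy: 0.433
GBM accuracy:        0.746
top features: [('7:P', 100.0), ('-5:C', 2.0008151492799326), ('-1:K', 1.647348689856446)]
```

The preset's three clusters are sequence-identical in distribution except
for the proline marker, so alignment scoring is nearly blind here (0.433,
below even the majority fraction 0.556) while boosting finds the marker:
`7:P` (proline at loop position 7; `-1` would denote the residue preceding
the loop) carries the maximum scaled importance of 100, and the boosted
model eliminates essentially all errors into and out of the cis cluster.

The same pipeline runs from the shell:

```bash
cdrcanon simulate --preset CIS_MARKER --seed 17 --out cis.tsv
cdrcanon benchmark cis.tsv --out report/ --seed 7 \
    --folds 5 --repeats 2 --inner-folds 3 --inner-repeats 1 \
    --n-trees 50 --n-trees 100 --depth 1 --depth 2
```

which writes per-group confusion matrices, the null-model category table,
feature importances and the geometry profile as TSVs under `report/`.

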