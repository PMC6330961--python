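# Methods

## Problem and data model

Non-H3 CDR loops of a given type and length adopt one of a few canonical
backbone conformations (clusters), plus a catch-all `"none"` class for
loops outside any cluster.  The unit of analysis is the **loop group** —
all records of one (loop type, loop length) pair — because clusters are
only defined within a group.  Input is a cluster-annotated table (one row
per non-redundant CDR: id, type, length, loop sequence, up to 10 flanking
residues per side, cluster label, optional per-residue φ/ψ in degrees); a
dialect configuration maps foreign column layouts onto the canonical
tab-separated schema, since annotated downloads do not share a fixed
header.  Rows containing non-standard residues (X, B, Z, gaps) are dropped
with a logged reason rather than imputed: both one-hot encoding and PAM30
scoring are defined only on the 20 standard residues.  Clusters with fewer
than three members are merged into `"none"` (`merge_sparse_clusters`,
idempotent); records arriving as `"none"` are kept as a regular class and
participate in training, evaluation and up-sampling like any other.

## blindBLAST baseline

Template selection by sequence similarity alone: the query is scored
against every same-type, same-length record and inherits the cluster of
the top-scoring template.  Scoring is exact Smith–Waterman local alignment
under PAM30 with affine gaps (open 9, extend 1 — a length-k gap costs
9 + k; the blastp defaults for PAM30).  On ≤ 55-residue flanked sequences
exhaustive dynamic programming is cheap, deterministic and strictly more
sensitive than word-seeded heuristic search, so no seeding heuristics,
E-values or composition statistics are involved; ranking by raw score is
order-equivalent to ranking by bitscore at fixed matrix and gaps.  The
kernel is a numba-compiled score-only DP; tests verify it exactly against
a naive pure-Python DP and against an independent alignment library.
Score ties are broken by lexicographically smallest template id, which
makes classification invariant to template order.  Queries are scored on
flanked sequences by default (matching how template databases used for
grafting store loops); loop-only scoring is a flag.  The default PAM30 is
taken from biopython's distributed copy of the NCBI matrix; any
NCBI-format matrix file can be substituted.

## Boosted-tree classifiers

Sequences are one-hot encoded over a loop-anchored window: position 1 is
the first loop residue, −1 the residue preceding the loop (no position 0),
downstream flank L+1 … L+10.  Feature names are `"position:residue"`
(e.g. `7:P`, `-1:G`), the residue alphabet is fixed alphabetically for
reproducible indices, and flanks shorter than 10 (chain termini) leave
all-zero blocks at the outermost positions — the window is anchored on the
loop.

One multiclass `GradientBoostingClassifier` is trained per group.
Hyper-parameters — number of trees, weak-learner complexity (encoded as
maximum tree depth), learning rate, minimum node size — are selected by
grid search in a nested repeated stratified CV: for each outer fold, an
inner repeated stratified CV on the outer-training partition scores every
grid point; the best point is refit on the full outer-training partition
and evaluated on the held-out fold; confusion tallies and accuracies are
averaged per repeat and then across repeats; the final model is refit on
all data with the grid point of highest mean inner accuracy.  The default
scheme is 3 repeats × 10 folds in both loops with grid
n_trees {50, 100, 200, 400} × depth {1, 2, 3} × learning rate {0.1} ×
min node size {5}; every piece is overridable.  Stratification guarantees
per-fold class counts within one sample of proportionality; classes
smaller than the fold count are spread one-per-fold.

**Imbalance handling.**  Within every training partition (outer-train and
inner-train independently, never held-out data), classes below
`T = min(50, majority size)` are up-sampled with replacement to T.
Applying the rule per-partition rather than globally is essential:
resampling before splitting would leak duplicated minority samples into
evaluation folds.  The nested-CV result records the resampled index
multiset per fold so the no-leakage guarantee is asserted in tests.
Whether `"none"` should be up-sampled like other minorities is not
settled; it is treated identically here.

**Feature importance.**  Importance is the ensemble's node-size-weighted
impurity reduction summed over all trees, linearly scaled so the maximum
is 100.  With gradient boosting the trees are regression trees on
gradients, so the impurity criterion is squared-error (Friedman) rather
than literal Gini; on the fixtures tested, importance-mass placement and
ranking coincide with an independent Gini stump computation, and that
agreement — not numeric equality of raw importances — is what the test
suite asserts.

**Determinism.**  Every RNG (fold shuffling, up-sampling, tree fitting,
simulation, generation) derives its seed from one master seed through a
single `SeedSequence`-based splitting scheme, so seeded runs are
bit-reproducible.

## Random-assignment null model and misclassification categories

The null assigns every query a predicted cluster drawn independently with
probability proportional to the empirical class frequencies.  The draw may
hit the true class (the diagonal is allowed); error counts are read off
the off-diagonal cells.  This multinomial variant, rather than a
permutation of the label multiset, is chosen because it makes the analytic
expectation `E[ε^{X→Y}] = n_X · P_Y` hold exactly.  The χ² goodness-of-fit
statistic sums `(obs − exp)² / exp` over off-diagonal cells; cells with
zero expected count are excluded with a warning.  Degrees of freedom are
set to the number of clusters, the convention this test was introduced
with for confusion tallies; the textbook choice (cells − 1) differs, and
the reported p-values should be read with that caveat.  Per-cell empirical
p-values use 10,000 simulated iterations with the indicator
`1{ε_obs ≥ ε_random}`, i.e. p is the fraction of simulated counts at or
below the observed count; categories split two-tailed at the 0.05 level
with inclusive boundaries (p ≤ 0.025 better than random, p ≥ 0.975 worse,
otherwise random-like).  No multiple-testing correction is applied across
misclassifications; raw p-values are reported with their category.

## Cluster geometry

The dihedral distance between equal-length loops is
`D(i,j) = Σ_{r=1..N} 2(1−cos(φ_r^i−φ_r^j)) + 2(1−cos(ψ_r^i−ψ_r^j))`,
summed over loop residues only (flanks never enter), angles in degrees at
the interface and radians internally; it is a symmetric premetric bounded
by 8N (the triangle inequality is not relied on).  The cluster exemplar is
approximated as the medoid — the member minimizing the summed distance to
all members, ties broken by smallest record id; externally supplied
exemplar ids are honored when available, since published exemplars are
defined by a density criterion this package does not reproduce.  The
cluster radius is the largest member-to-exemplar distance, and a
structural neighbor is any other member strictly closer to the query than
`radius / 15`; the 1/15 fraction is a configurable default chosen for its
discriminative value between correctly and incorrectly classified queries.
A zero-radius multi-member cluster yields zero neighbors with a warning.

## Synthetic data generator

The generator emulates the features of real cluster-annotated groups that
drive classifier behavior: per-(type, length) groups with one dominant and
several sparse clusters, cluster-specific position motifs (residue
probability vectors at loop-anchored positions, flanks included), and
per-residue dihedrals drawn from a wrapped normal around cluster-specific
(φ, ψ) centers chosen from representative backbone conformations
(α, β, PPII, left-α), default dispersion 10°.  Background positions draw
uniformly from the 20 residues (overridable).  It does not emulate real
antibody residue frequencies, framework numbering, redundancy structure,
or correlated angle noise — so passing tests demonstrate correctness of
the machinery and qualitative phenomena, not real-data accuracy levels.

Four presets define the study conditions used throughout tests and the
acceptance script, sized for desk-scale runs:

- **DOMINANT** — 600 loops (H1-13), 85/10/5% across three clusters, each
  carrying a deterministic three-residue signature: sequence-separable, so
  a sound classifier should approach perfect outer accuracy.
- **BALANCED_PAIR** — two equally populated clusters (140/140) plus a
  sparse tail (20), motifs at strength 0.9.
- **CIS_MARKER** — 270 loops (L3-9): one cluster with proline always at
  loop position 7, the others never; all other positions share one
  background.  Alignment scoring is nearly blind to a single-position
  marker while boosting isolates it — the qualitative phenomenon that
  motivates learning cluster labels explicitly.
- **INSEPARABLE** — identical sequence distributions, distinct angle
  centers (70/30): the majority fraction is the accuracy ceiling for any
  sequence-based method.

## Numerical and design choices

- Angles are stored in degrees in (−180, 180], converted to radians only
  inside distance evaluation; table round trips preserve dihedrals at
  3-decimal precision.
- Prediction ties break by lexicographic class order (probability argmax
  returns the first maximum over sorted classes).
- The scaled importance maximum is pinned to exactly 100 to absorb
  floating-point drift in the rescaling.
- Desk-scale evaluation runs (tests, acceptance script, README example)
  use 5 outer folds × 1–2 repeats, inner 3-fold × 1 repeat, and the grid
  n_trees {50, 100} × depth {1, 2}; these are the package's default
  problem sizes for the bundled presets, while the library defaults keep
  the full 3 × 10 nested scheme for real datasets.
- The classifiers are scikit-learn estimators (`BlindBlastClassifier`,
  `UpsampledGradientBoosting`, `OneHotCdrEncoder`) and compose with
  sklearn model selection; the module-level functions are thin wrappers.

## Known limitations

- The medoid exemplar can differ from a density-based exemplar in diffuse
  clusters; the override hook exists for externally defined exemplars.
- Accuracy on real cluster-annotated databases depends on properties the
  generator does not model (true motif strength, redundancy filtering,
  species composition); numbers reported by the acceptance script
  characterize the presets, not any external database.
- χ² p-values inherit the non-standard degrees-of-freedom convention noted
  above.
- Up-sampling with replacement duplicates minority records; alternatives
  (synthetic minority generation, under-sampled weak learners,
  distance-weighted losses) are out of scope.
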