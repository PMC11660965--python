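# Methods

## Problem and model

The package predicts unobserved miRNA–disease associations from three inputs:
a binary adjacency `A` (`n_m` miRNAs x `n_d` diseases) of experimentally
validated associations, a precomputed miRNA functional-similarity matrix
(MFS) and a precomputed disease semantic-similarity matrix (DSS), both square,
symmetric, with entries in [0, 1].  The task is binary classification of
(miRNA, disease) pairs with calibrated probability outputs, used both for
cross-validated performance estimation and for ranking candidate miRNAs for a
single disease.

### Similarity construction

Gaussian interaction-profile (GIP) kernels measure profile similarity on the
adjacency itself: `K(i, j) = exp(-γ ‖IP_i − IP_j‖²)` with the bandwidth
normalised by the mean squared profile norm, `γ = γ' / ((1/n) Σ ‖IP_i‖²)` and
`γ' = 1`.  The normalisation makes the kernel scale adapt to the density of
the association matrix; an all-zero profile set leaves the bandwidth undefined
and is rejected as degenerate.  Fusion averages the curated similarity with
the GIP kernel wherever the curated entry is nonzero and falls back to the
GIP value where it is exactly zero.  Zero is the curated matrices' encoding
for "no similarity information", so the fallback branch, not the average, is
what handles missing annotations; a zero on the curated diagonal likewise
falls back to the GIP diagonal of 1, keeping the fused diagonal exactly 1.

### Pair features

Each pair `(i, j)` is represented by the concatenation
`[SM_i | A_·j | SD_j | A_i·]` — the miRNA's fused-similarity row and the
disease's interaction profile (the miRNA-side block, `2 n_m` columns),
followed by the disease's fused-similarity row and the miRNA's interaction
profile (`2 n_d` columns).  The concatenation reading of the feature
definition is fixed by the block widths it must produce (990 and 766 at the
495 x 383 reference dimensions, 1,756 in total).  Training sets are balanced:
every known association is a positive and an equal number of unknown pairs is
drawn uniformly at random, once per experiment, seeded.  Per-fold negative
resampling is available as an option but is not the default, matching the
single-undersampling protocol of the headline experiments.

### Dimensionality reduction

Mean-centred PCA; the retained component count is the smallest `k` whose
cumulative explained-variance ratio reaches the threshold (default 0.95,
implemented as `>=` so an exact hit counts).  If numerical rank truncation
leaves the total below the threshold, all components are kept with a warning.
Components follow a deterministic sign convention (largest-magnitude loading
positive) so that projections are bit-reproducible across runs and BLAS
builds.  A threshold-scan utility reports `k` over a 5%-step grid.

### Cascade forest

Each level holds four estimators — two random forests, AdaBoost over depth-1
decision trees, and a gradient-boosted tree ensemble — with 50 trees each
(200 trees per level).  The gradient-boosted member is treated as a pluggable
estimator contract (fit / predict-probability with a tree count); the
implementation binds scikit-learn's gradient boosting, since all features at
this point are continuous and categorical-aware machinery would be inert.
AdaBoost uses depth-1 trees as the canonical reading of "50 decision trees".

Every estimator is fitted with stratified inner 5-fold CV; held-out rows
receive that fold-model's class-probability pair, so each training row gets
8 out-of-fold probability columns produced by models that never saw it.
Level `t+1` consumes the level-0 features concatenated with level `t`'s
augmentation — the augmentation is replaced between levels, never stacked, so
the width stays `p + 8`.  Growth stops when the inner-CV accuracy of the
averaged-estimator vote fails to improve by more than `improvement_tolerance`
(default 1e-4) or at `max_levels` (default 10); the retained depth is the
accuracy argmax.  At inference each level's augmentation is the mean of its
fold-models' predicted probabilities — matching the distribution of the OOF
features the next level was trained on, and avoiding a full-data refit that
the training procedure never defines.

The terminal predictor is a polynomial-kernel SVM (degree 3, `gamma="scale"`,
features standardised) fitted on the retained level's augmented features.  A
margin classifier has no native probabilities, so a logistic (Platt-style)
calibration is fitted on out-of-fold decision values from an inner 5-fold
loop, and applied to the final SVM's decision values at prediction time.  By
default the SVM sees the `p + 8` augmented features; an `augmentation_only`
flag restricts it to the 8 probability columns.  A `mean_oof` terminal option
bypasses the SVM and returns the averaged estimator probability; it exists as
a structural test hook (a one-forest, one-level cascade must reduce exactly
to that forest's averaged fold probability).

All randomness descends from a single integer seed through spawned
`SeedSequence`s (per level, per estimator, per CV fold), so identical
configuration and seed give bitwise-identical out-of-fold matrices, depths
and scores.

## Evaluation protocols

Point metrics (Acc, Pre, Rec, F1) use the standard confusion-matrix formulas
at a fixed 0.5 threshold on calibrated probabilities; zero-denominator
metrics are reported as NaN with a warning rather than silently coerced.
AUC is the rank (Mann–Whitney) statistic with ties counted half; AUPR is the
area under the precision–recall step curve swept in descending score order,
without interpolation.

Two modes are exposed and labelled in every report:

- **paper** (default for reproduction runs): GIP kernels are computed from
  the full adjacency and PCA is fitted on the full balanced table before the
  CV split.  This matches the apparent headline protocol but lets test-fold
  information reach the fitted transforms.  A second, unavoidable leakage
  channel is intrinsic to the feature definition itself: a test pair's own
  adjacency entry appears inside its `A_·j` / `A_i·` blocks (at row-dependent
  positions).  Cross-validated scores in this mode are therefore optimistic
  relative to truly prospective prediction.
- **leakage_safe** (default recommendation for new analyses): PCA is refitted
  inside each training fold; a training-masked GIP option exists in the
  similarity layer.

### Leave-one-disease-out ranking

The case-study protocol masks the target disease's entire adjacency column
*before* anything else is computed, so its known links cannot leak through
the GIP profiles, the fusion, or the sampled training set; similarity
matrices are recomputed from the masked adjacency for the same reason.  The
masked column is also excluded from negative sampling: its pairs are exactly
the candidates being scored, and labeling a random subset of them negative
measurably biases the ranking against them.  All `n_m` candidate pairs are
scored and sorted (ties broken by miRNA id).

A known limitation at small problem sizes: candidate rows carry an all-zero
disease-profile block that never occurs in training, i.e. they are
out-of-distribution.  With PCA in the loop the rotation entangles that shift
with the informative features, and on the 60 x 40 synthetic dataset a
minority of fits invert the planted ranking outright; the same forest on raw
features recovers the planted block almost always.  The pipeline keeps PCA
(it is part of the method), but per-disease rankings at desk scale should be
read with this instability in mind; it shrinks as `n_d` grows because the
masked column becomes a vanishing fraction of the feature space.

## Synthetic data

The generator plants co-clusters: miRNAs and diseases are partitioned into
`n_blocks` equal blocks (remainder to the last), a co-clustered pair is
associated with probability 0.6 versus 0.05 background, and similarity is
0.7 within versus 0.15 between blocks plus clamped uniform noise (±0.05),
symmetrised, unit diagonal.  A fraction (default 10%) of off-diagonal
similarity entries is forced to exactly zero to exercise the fusion fallback;
setting it to 1 makes fusion return the GIP kernel everywhere off-diagonal.
Defaults (60 x 40, 4 blocks, seed 1) give an adjacency density near 0.19 —
a few hundred positives, i.e. roughly nine hundred balanced training rows —
small enough that the full tuned pipeline cross-validates in well under a
minute per run.  Within/between similarity levels were chosen to mimic the
bimodal structure of curated functional-similarity matrices (high within
disease-functional families, low elsewhere); they were fixed once at
generator-design time.

What passing on this generator shows: the pipeline detects planted low-rank
block structure through the full similarity → features → PCA → cascade path,
is calibrated enough to score at chance under permuted labels, and all
bookkeeping (balancing, OOF augmentation, depth selection) behaves as
specified.  What it does not show: performance on real HMDD-derived data,
whose degree distribution is heavy-tailed rather than block-uniform, whose
similarity matrices have structured (not uniform) missingness, and whose
positives are biased toward well-studied miRNAs and diseases.  The generator
makes no attempt to match HMDD's empirical degree distribution.

## Numerical choices and degenerate inputs

- Similarity validation tolerances: symmetry and unit-diagonal checks at
  1e-10; GIP kernels are explicitly symmetrised and their diagonal pinned to
  1 to absorb floating-point asymmetry from the distance computation.
- Probability pairs from every estimator sum to 1 within 1e-9 per row (the
  estimators emit normalised class probabilities; the invariant is asserted
  in tests).
- Degenerate inputs rejected with specific errors: all-zero profile sets
  (GIP bandwidth undefined), constant feature matrices (PCA undefined),
  single-class labels and folds, negative sampling beyond the number of
  zeros.
- "Improvement" in cascade growth is a strict `> tolerance` gain over the
  best accuracy so far; the first level is always kept.
- Ranking ties are broken lexicographically by miRNA id for determinism.

## Problem sizes used in the shipped checks

Structural identities are verified at the real reference dimensions
(495 x 383, 5,430 positives) — these are dimension computations and run in
seconds without materialising the full 189,585-row feature matrix.
Statistical checks run on the generator defaults (~900 balanced rows, 200
raw features): 5-fold CV of the full tuned pipeline takes ~40 s per run on
one CPU, and the planted-signal (AUC >= 0.90) and permuted-label
(AUC in [0.40, 0.60]) checks are run at seeds 1–3.
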