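# Methods

This note documents the models and procedures implemented in
`methylens`, the numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Problem setting

DNA methylation arrays measure, per CpG probe, a beta value in [0, 1]
(methylated / total intensity). Tumor-classification cohorts are wide
and shallow: thousands of samples at most, hundreds of thousands of
probes, and often dozens of diagnostic classes with very unequal sizes.
The package builds multiclass classifiers on such matrices, converts
their raw scores into calibrated posterior probabilities, and evaluates
everything under a nested cross-validation protocol that keeps feature
selection inside the training folds.

Matrices are oriented samples-in-rows everywhere. Beta values are
validated to [0, 1]; M-values and generic omics matrices are accepted
unchecked (`value_type="mvalue"` / `"generic"`), since every model here
is agnostic to the value scale. Missing values are rejected rather than
imputed — imputation is a preprocessing concern with its own literature,
and silently filling values inside a classifier package invites leakage.

## Ensemble SVM (eSVM) and eNeural

A soft-margin linear SVM separates sparse, high-dimensional methylation
samples well, but its kernel evaluations make training expensive as the
probe count grows. The eSVM wrapper trains `B` one-vs-one linear SVM
base learners, each on *all* samples but on a random probe subset of
size `m` drawn without replacement, independently per learner. The
ensemble posterior is the arithmetic mean of the base posteriors,
renormalized. Feature subsampling shortens the vectors entering the
inner products x_i^T x_j while leaving the margin geometry largely
intact, which is why the union of the base learners' support vectors
reliably covers the plain SVM's support-vector set (verified in the
acceptance studies at B=20, m=p/2).

Choices, with defaults:

- **Multiclass scheme** — one-vs-one with a Platt sigmoid per class
  pair, fitted by penalized maximum likelihood (Lin–Lu–Weng Newton
  iteration with smoothed targets) on the *training* decision values,
  then pairwise coupling (Wu–Lin, second formulation, solved via its
  KKT linear system). This keeps training deterministic given the
  input order; the cross-validated Platt fit inside
  `sklearn.svm.SVC(probability=True)` is deliberately not used.
- **C = 1.0** for all pairwise machines.
- **m = min(p, 1000)**, **B = max(10, ceil(p/m))**, so the expected
  probe coverage of the ensemble is at least one.
- **No sample bootstrap by default** (a flag exists). Every learner
  sees all samples; only features are bagged. This is what makes the
  support-vector union argument meaningful.
- Sampled probe subsets are **sorted by column index**, so that the
  degenerate ensemble (B=1, m=p) reproduces the plain SVM *bitwise* —
  this exact reduction is the primary oracle for the wrapper.

eNeural is the same wrapper around a multilayer-perceptron base: one
hidden layer of 128 ReLU units, softmax output, cross-entropy, trained
by full-batch Adam (lr 0.01) for a fixed budget of 200 epochs, with
seed-controlled initialization. The net is a compact numpy
implementation, which keeps it deterministic and bit-exactly
serializable.

Random forest, XGBoost and elastic-net logistic regression are exposed
as pluggable base kinds backed by their standard implementations; their
internals are out of scope here.

## Probability calibration

Raw multiclass scores are mapped to calibrated posteriors by one of
three calibrators, always fitted on out-of-fold (OOF) scores:

- **LR** — per class k, a univariable logistic regression of the
  one-vs-rest indicator on the logit of the class's own raw score
  (clipped at 1e-12), outputs renormalized. Under complete separation
  the slope diverges; the fit is capped at 100 Newton steps and flagged
  (vanishing gradient with |beta| > 12 also counts as divergence, since
  at separation the gradient vanishes *because* the slope blows up).
- **FLR** — the same design with Firth's penalty: the objective is
  l(b) + 1/2 log det I(b), maximized by Newton steps on the modified
  score U*_r = sum_i (y_i − pi_i + h_i(1/2 − pi_i)) x_ir with step
  halving. Estimates are finite on any finite data set, including
  separable ones; on a 2×2 design the slope equals the log odds ratio
  of the half-cell-corrected table, which serves as a closed-form
  oracle.
- **MR** — multinomial logistic regression with ridge penalty
  lambda·||b||² on the full K-column raw score matrix (raw
  probabilities, not logits), lambda selected by 5-fold CV minimizing
  multiclass log loss over a 25-point grid 10^-4…10^4. Backed by
  `sklearn.LogisticRegression` with C = 1/(2·lambda); as lambda → inf
  the calibrated rows collapse to the class-frequency vector (tested).

Inside nested CV, the calibrator for each outer fold is fitted on the
pooled inner-fold OOF scores of that fold's training set and applied to
the fold's raw test scores; base models and fold partitions are never
refitted during calibration.

## Feature selection

- **topvar** — probes ranked by unbiased (n−1) sample variance.
- **limma-style moderated F** — per probe, a one-way group-means model;
  the F denominator is the posterior variance
  s̃² = (d0·s0² + d·s²)/(d0 + d), with the inverse-chi-square prior
  (d0, s0²) estimated by moment matching on log s² (digamma/trigamma
  closed forms, Newton trigamma inverse). When the observed log-variance
  dispersion does not exceed chi-square sampling noise, d0 = inf and all
  variances shrink to their mean. The implementation matches
  Bioconductor limma's `eBayes` F to ~1e-14 relative on both branches
  (cross-checked via Rscript in the test suite). `d0=0` reduces exactly
  to the ordinary ANOVA F, which is also exposed as **anova** (the
  selector used for the MOGONET comparisons).
- **scmer-style manifold preservation** — non-negative probe weights w
  minimize KL(P ‖ Q(w)) + l1·||w||₁ + l2·||w||₂², where P is the
  symmetrized, perplexity-calibrated t-SNE affinity matrix of the
  samples on all probes (per-point precisions by binary search), and
  Q(w) is the same kernel with the same precisions on distances
  ||w ⊙ (x_i − x_j)||. At w = 1, Q = P and the KL term is zero.

  Numerical choices that matter:
  - Optimization is projected gradient on w ≥ 0 (analytic gradient,
    verified against finite differences), with a backtracking line
    search under the proximal majorization condition. The stricter
    acceptance rule is essential: because distances depend on w², the
    KL gradient component for probe g scales with w_g, so **w_g = 0 is
    an absorbing state** — a wild step that kills probes can never be
    undone. Max 500 iterations, relative-loss tolerance 1e-6,
    initialization w = 1; the loss trace is recorded and is
    monotonically non-increasing.
  - The l1 strength is tuned along a **warm-started continuation
    path**: l1 increases geometrically from 0, each solve starting from
    the previous solution, until the count of weights > 1e-6 drops into
    ±10% of the target; the bracketing interval is then bisected (40
    solve budget, nearest achieved count + warning flag on failure).
    Fresh-start bisection fails here because the count-versus-l1 curve
    has cliffs. A fixed `lam1` can be passed to bypass the search.
  - Default l2 = 0.1 and perplexity 30 (capped at (n−1)/3). The ridge
    term is what spreads weight across *redundant* informative probes;
    with pure l1 the optimizer keeps an arbitrary subset of them and
    spends the remaining budget on noise probes whose neighborhood
    detail is unique. Robustness was checked over l2 in [0.03, 0.3].

  Manifold-preserving selection needs enough samples for the affinity
  matrix to be signal-dominated: at n ≈ 50 the within-cluster
  neighborhood structure of the synthetic data is noise-driven and no
  implementation recovers planted probes reliably; the recovery study
  therefore uses n = 120 with perplexity ≈ n/3.

- **Probe→gene mapping** keeps probes annotated TSS200 / TSS1500 /
  1stExon (promoter regions) and returns their unique gene symbols,
  reporting the count of unannotated probes skipped.
- **Pseudo-omics split** partitions probes into promoter / gene body /
  other groups (unannotated probes fall into *other*), each treated as
  an omic for the multi-omics models; an empty group is an error since
  no per-omic learner could be trained on it.

Ties in every ranking are broken lexicographically by probe ID for
cross-platform reproducibility.

## Nested cross-validation and evaluation

`make_nested_folds` builds a stratified outer × inner plan (default
5 × 5) by seeded within-class shuffling and round-robin dealing, so
per-fold class counts deviate from proportionality by at most one
sample; every class must have at least `outer` samples.

`run_nested_cv` refits feature selection *inside each outer training
fold*; its interface accepts selector specifications only — a
precomputed feature list is rejected, which is the leakage guard.
Outer-test predictions are concatenated into an OOF probability matrix
per (model, feature) pair; optionally the inner folds produce the OOF
scores needed for calibrator training. Metrics per variant:

- misclassification error (argmax with lexicographic tie-break),
- Brier score in its unnormalized multiclass sum-of-squares dialect
  (range [0, 2]),
- mLogloss with probabilities clipped at 1e-15.

Further evaluation operations: arithmetic-mean aggregation of several
classifiers' probability matrices (the multi-classifier "unified"
prediction); confidence stratification into [0, 0.7], (0.7, 0.8],
(0.8, 0.9], (0.9, 1] bins against a reference classifier's confidence
scores; grouping of predicted classes with ≤ 10 samples into an
"others" class; internal cluster-validity indices (mean silhouette,
Calinski–Harabasz, Davies–Bouldin; Euclidean, singleton clusters score
zero silhouette) computed on whatever feature or embedding space the
caller supplies, since the right space is a modelling choice; and
per-class two-sided Fisher exact enrichment of a sample subset with
sample odds ratios (reported as inf for empty off-cells). The index and
metric implementations are checked against independent brute-force
reimplementations at 1e-10…1e-12.

## Multi-omics models

**Multi-omics eSVM/eNeural**: each omic of an aligned bundle
contributes `learners_per_omic` base learners whose probe subsets are
drawn within that omic only; aggregation is the usual ensemble mean. A
single-omic bundle reduces exactly to the plain ensemble. Subset sizes
are clamped to the omic's width with a warning.

**MOGONET-style GCN fusion**: per omic, a cosine-similarity sample
graph is built by thresholding at the similarity that retains
approximately `k·n/2` edges (target mean degree k = 10, negative
cosines never form edges), normalized as
Â = D̃^{-1/2}(A + I)D̃^{-1/2}. A two-layer graph convolutional network
H1 = ReLU(Â X W1), logits = Â H1 W2 is trained transductively — the
graph contains training and test nodes, and only labelled (training)
nodes contribute to the cross-entropy. Defaults: hidden width 64,
learning rate 1e-3, 300 epochs, full-batch Adam, no dropout. The
networks are numpy implementations with hand-derived gradients; all
training is seed-deterministic.

Per-omic class-probability outputs are fused by a small fully connected
network in one of two modes: **concat** (per-learner probability
vectors concatenated) or **interaction** (outer product of the per-omic
mean probability vectors, dimension K^M, capped at 10 000). The
**auto** mode uses interactions only when K ≤ 2, since the interaction
dimension explodes with the class count; the concat mode compensates by
assigning each omic several GCN learners (default 3). With one omic and
one learner there is nothing to fuse and the learner's posterior is
returned directly. When used inside cross-validation the graph must be
rebuilt per fold over training + test nodes with test labels masked;
the package exposes the training-sample list as an explicit argument to
make this unambiguous.

## Embeddings and the pan-cancer concordance filter

PCA embeddings fix the sign of each axis by making its
largest-magnitude loading positive, so results are fully deterministic.
t-SNE runs a standard gradient optimization (early exaggeration 4× for
100 iterations, momentum 0.5→0.8, learning rate 200, seeded 1e-4 normal
initialization) on a given affinity matrix. The **joint embedding**
computes per-omic symmetrized affinity matrices at a shared perplexity,
averages them (unweighted by default; a weight vector is exposed),
renormalizes, and optimizes a single layout — a single-omic bundle
reduces to ordinary t-SNE, and duplicating an omic is equivalent to
doubling its weight.

`grid_cluster` splits the embedding bounding box into g × g equal cells
(default g = 30) and merges occupied cells into 8-neighbour connected
components; every sample belongs to exactly one component.
`label_clusters_filter` assigns each cluster its modal histological
label and keeps only samples whose label matches it; clusters with a
tied mode are dropped entirely — the conservative reading of "keep only
samples with a matching relationship". The g parameter is the single
tuning knob of this reconstruction.

## Synthetic data

`gen_methyl_dataset` emulates a methylation cohort at desk scale:
background probes are i.i.d. Beta(2, 2) (mid-range mean, realistic
spread, deliberately not bimodal), and each class owns a block of
informative probes whose draws are shifted by ±delta (sign drawn per
probe) for that class's samples, clipped to [0.01, 0.99]. Class sizes
follow largest-remainder apportionment of the requested proportions.
One global seed drives named substreams for the matrix, the labels, the
signs and each omic, so changing one omic's seed changes only that
omic. `gen_multiomics_dataset` builds aligned bundles with per-omic
informativeness; `degrade_scores` raises probability rows to the power
1/T and renormalizes, a deterministic miscalibration fixture (T = 1 is
the identity; T → inf gives uniform rows).

What the generator does *not* emulate: the bimodal beta-value mixture
of real arrays, probe-probe correlation (CpG islands), batch effects,
class imbalance at the 91-class scale, and measurement noise that
depends on methylation level. Passing tests therefore demonstrate
correctness of the algorithms and the claimed relative behaviours
(e.g. eSVM ≈ SVM, calibration reduces mLogloss), not clinical-grade
accuracy on real cohorts.

## Validation studies and problem sizes

The suite's end-to-end studies (also recomputed by
`scripts/acceptance.py`) use these sizes, chosen to finish in minutes
on one CPU while keeping each effect comfortably measurable:

- eSVM→SVM reduction: 100 × 50, K = 3; agreement to 1e-10.
- Accuracy parity under 5 × 5 nested CV: 200 × 500, K = 4,
  delta = 0.3, 5 seeds; |err(eSVM) − err(SVM)| ≤ 0.02 with both within
  0.01 of RF, in ≥ 4 of 5 seeds.
- SV coverage: 150 × 300, K = 3, B = 20, m = 150; union coverage ≥ 0.9
  every seed.
- Firth closed form: 50 random 2×2 tables, 1e-6.
- Calibration: n = 300, K = 5, temperature-3 degraded OOF scores;
  MR strictly reduces held-out mLogloss.
- Feature recovery: moderated-F on n = 90, p = 200, 10 planted probes
  (≥ 9/10 in ≥ 95% of 50 seeds); manifold-preserving on n = 120,
  p = 100, 10 separating probes (≥ 8/10 in ≥ 90% of 20 seeds).
- Fusion: 3 omics (one pure noise), n = 150; multi-omics eSVM error no
  worse than its worst single omic, GCN-concat accuracy ≥ 0.9.
- Concordance filter: 1712-sample embedding surrogate, 30 well-
  separated blobs, 30% planted label noise; kept fraction within 10%
  of the planted concordant fraction.

## Known limitations

- The SCMER-style selector optimizes a non-convex objective; the
  continuation path makes the selected set deterministic per seed and
  data, but it is a local optimum, and the achieved feature count can
  miss the ±10% band on pathological inputs (flagged, never silent).
- The GCN is transductive; predictions exist only for samples present
  in the training graph. Inductive prediction would require graph
  extension, which is out of scope.
- LR/FLR calibrate each class against its own score only; classes whose
  raw scores are informative mainly through *other* classes' columns
  are better served by MR.
- `model_roundtrip` is bit-exact for the package's own models; the
  pluggable rf/xgb/elnet kinds serialize their opaque estimators via
  joblib, so bit-exactness across library versions is not guaranteed
  for them.
- Runtime benchmarking of eSVM versus SVM is explicitly not reproduced;
  the package demonstrates the accuracy and support-vector claims,
  which are hardware-independent.
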