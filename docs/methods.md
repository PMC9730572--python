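# Methods

This note documents the models implemented in `camrisk`, the parameters
that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## 1. Convex-mixture deconvolution

**Model.** Bulk expression is a noisy convex mixture `X = A·S`
(samples × genes = samples × K · K × genes).  Rows of `A` live on the
probability simplex; `S` is nonnegative, linear-scale expression.
Identifiability relies on *marker separability*: every subclone owns
genes it expresses far more strongly than any other subclone.  Under
that assumption, scaling each gene's cross-sample vector `x_g` to unit
sum places genes inside a (K−1)-simplex whose corners are the unit-sum
scaled columns of `A`, with marker genes at the corners.

**Algorithm.**

1. *Filtering* (`preprocess_expression`): drop genes with mean below the
   1st percentile of gene means, keep the top 2000 by variance.  These
   defaults are declared, not derived; both are configurable.  Input
   must be linear-scale nonnegative — a matrix whose maximum is below 30
   triggers a log-scale warning but is never transformed silently.
2. *Aggregation* (`cluster_gene_vectors`): k-means with 50 clusters and
   a fixed seed condenses the gene cloud to centre vectors.  k-means was
   chosen over affinity-propagation-style aggregation for determinism
   and speed; the cluster count is a resolution parameter, not a model
   order.
3. *Corner search* (`find_corners`): the margin of a candidate corner
   set is the summed NNLS residual of all other centres regressed on the
   corners — zero exactly when the remaining centres lie in the corners'
   conic hull.  All C(L, K) subsets are enumerated when C(L, K) ≤ 10⁵;
   otherwise greedy forward seeding followed by pairwise swaps to a
   local optimum.  On every instance small enough to check, the greedy
   path reproduces the exhaustive optimum (tested at L = 12, K = 4).
4. *Estimation* (`estimate_A_S`): initial `A` stacks the corner centres
   as columns, renormalising each sample row to unit sum; `S` solves
   per-gene NNLS.  Because markers have finite dominance, corner centres
   carry a small symmetric contamination from the other subclones; up to
   30 alternating refinement passes (re-solve `A` rows on `S`,
   renormalise, re-solve `S`), stopped early at a relative RSS
   improvement below 1e-6, remove it.  On noiseless separable input this
   restores the exact factorisation (RSS at the numerical floor) and
   permutation-matched fraction correlations ≥ 0.99.
5. *Model order* (`select_K`):
   `MDL(K) = (ng/2)·ln(RSS/ng) + (P/2)·ln(ng)` with
   `P = n(K−1) + Kg` free parameters, minimised over K = 2..8, ties
   broken toward smaller K.  Residuals at or below 1e-12·‖X‖² are
   treated as numerically exact fits (MDL −∞), which makes degenerate
   single-subclone inputs collapse to K_min instead of chasing rounding
   noise.
6. *Projection* (`project_fractions`): new cohorts are regressed
   per-sample on a fixed reference's rows (NNLS over the shared genes)
   and renormalised; all-zero solutions are flagged and given uniform
   fractions.
7. *Markers* (`marker_genes`): genes are attributed to their nearest
   corner; within each corner group the nearest `margin_quantile`
   fraction is kept, so lists are disjoint by construction.

Subclone labels are arbitrary; comparisons against ground truth use
Hungarian matching on the fraction-column correlation matrix
(`match_subclones`).

## 2. Risk stratification and survival statistics

**Consensus clustering** follows the resampling scheme of Monti-style
consensus: 500 rounds of 80% subsampling without replacement, k-means on
the fraction rows per round, co-clustering counts normalised by
co-sampling counts.  The cluster number minimises PAC, the fraction of
off-diagonal consensus entries strictly inside (0.1, 0.9); a fixed K
mode is available since the analysis design may fix two groups a priori.
Final labels cut an average-linkage tree of 1 − consensus.

**Risk naming** (`assign_risk_labels`): when survival is available the
cluster with the smaller Kaplan–Meier median is "high"; otherwise the
cluster with the higher mean fraction of the adverse subclone (by
default the subclone whose mean differs most between clusters — in the
generator that is the ECM-like component).  The applied rule is always
recorded in the output metadata.

**Statistics.** The Kaplan–Meier estimator is delegated to lifelines;
the two-group log-rank test is computed in-package from the O−E / V
tabulation (validated against a hand-worked example and lifelines); Cox
proportional hazards maximises the Breslow-tie partial likelihood by
Newton iteration with step halving, stopping when the gradient norm
falls below 1e-8·(1 + |log L|), and reports Wald 95% CIs.  The score
statistic at β = 0 for a binary covariate reproduces the log-rank
chi-square to 1e-6 (classical identity, used as an internal consistency
oracle).  `optimal_cutpoint` scans every observed threshold leaving at
least `minprop = 0.1` of samples per side and maximises the absolute
standardised log-rank statistic, ties toward the lower threshold.
Covariates follow the standard clinical codings (sex M vs F, CEA
abnormal vs normal, grade middle+high vs low, stage III+IV vs I+II).

## 3. Radiomic signature and classifier

**LASSO-Cox** (`lasso_cox_select`): features are z-scored; the L1 path
is fitted with scikit-survival's coxnet (the glmnet-equivalent), and the
penalty is chosen by seeded, event-stratified 10-fold cross-validation
of the partial-likelihood deviance `−2·(ℓ(all) − ℓ(train))`, by either
the `min` or the `1se` rule (default `1se`; `min` gives fuller recall).
A grid value of 0 is fitted unpenalised via the in-package Newton solver
so the λ → 0 limit matches ordinary Cox regression.  Selected features
are returned in decreasing coefficient magnitude.

Support recovery has a structural limit worth stating: when several
"informative" features are noisy proxies of one underlying risk
variable, L1 selection keeps a representative subset rather than all of
them — denser recovery requires features with conditionally independent
prognostic signal.  The synthetic generator's informative features are
exactly such proxies (see §5), so recovered counts below the planted
count on that generator reflect the statistics of L1 selection, not an
implementation defect; R's `cv.glmnet` behaves identically on the same
data.

**ELM** (`elm_train` / `elm_predict`): hidden weights and biases are a
seeded standard-normal draw, `H = σ(XW' + b)` with sigmoid (default) or
tanh activation, and output weights solve the ridge-stabilised normal
equations `(H'H + 1e-8·I)β = H'T` against one-hot targets; prediction is
argmax with scores exposed.  With n_hidden ≥ n the network interpolates,
so training accuracy on the study-scale cohorts is ~1.0; the stored
per-feature standardisation makes predictions invariant to affine input
rescaling and feature order.  Models serialise to JSON (weights, seed,
feature names, standardisation).

## 4. Radiomics subset

Only a declared subset is implemented — the two named features plus
first-order statistics; arbitrary precomputed tables are the supported
path for anything else.

* Discretisation: fixed bin width (default 25, the common CT choice),
  `level = floor((v − min)/w) + 1`; shift-invariant.
* `surface_volume_ratio`: volume is voxel count × voxel volume; the
  surface triangulates the 0.5 iso-surface by marching cubes after a
  σ = 1 voxel Gaussian anti-aliasing of the binary mask (the raw binary
  iso-surface carries a ~9% staircase area inflation that does not
  vanish with resolution; smoothing brings digitised spheres within
  ~2-3% of the analytic 3/r).  A voxel-face-count mode is exact for
  axis-aligned solids and serves as the discrete oracle.
* GLDM: dependence of a voxel = number of in-mask Chebyshev-distance-1
  neighbours (configurable) whose level differs by ≤ α (default 0);
  `P(i, j)` accumulates counts; Dependence Entropy is the Shannon
  entropy (bits, ε = 1e-16 guard) of the normalised matrix.  Verified
  against the exhaustive neighbour count of the constant 3×3×3 cube
  (8·j7, 12·j11, 6·j17, 1·j26).
* First order: mean, population variance, moment skewness (0 for
  constant regions), discretised-level entropy, energy, min, max.

Images and masks share index space; spacing converts to mm; no
resampling is performed.

## 5. Synthetic cohorts

The generator plants exactly the structure the method assumes, with
known ground truth:

* **Reference**: K × genes, background U(0.5, 4); each subclone owns 30
  marker genes on which its value is ≥ 5× the other subclones' maximum
  (fold and background scale configurable; zero background gives pure
  markers for exact-recovery oracles).
* **Fractions**: group-specific Dirichlets.  The two-group prognostic
  composition uses α = (5, 5, 5, 1) for low risk and (2, 2, 2, 12) for
  high risk: high-risk tumours carry a dominant adverse (ECM-like)
  subclone, with a between-group gap of ~0.6 in that component at
  within-group spread ~0.1 — clearly separated compositions, as the
  consensus-recovery design requires.
* **Expression**: `X = A·S` plus additive Gaussian noise clipped at 0
  (default sd 2% of the mean signal); log-normal multiplicative noise is
  available.  Real cohorts' noise levels are not known; these defaults
  are chosen for testability, not fidelity.
* **Survival**: exponential event times with hazard
  `λ·exp(log HR·1[high])` (defaults λ = 0.02/month, log HR = 1.0);
  censoring uniform on (0, c) with c solved by root finding so the
  expected censored fraction hits the target (default 30%).  Covariates
  are drawn independently of outcome, so they are exchangeable nulls in
  multivariable models.
* **Radiomic features**: 100 standard-normal columns; 11 informative
  ones are shifted by 1.5 in the high-risk group (optionally also tied
  linearly to a fraction column).  Because the shift acts on the group
  mean — features predict the risk *label*, they do not drive hazard
  independently — the informative features are exchangeable proxies with
  pairwise correlation ≈ 0.36, which is what bounds L1 support recovery
  (§3).
* **Images**: analytic spheres/ellipsoids/boxes on a voxel grid with
  constant or textured interiors, so shape features have closed-form
  oracles.

Cohort scales default to the study sizes (n = 200 development, n = 236
radiogenomic with equal risk groups).  What passing tests on this
generator shows: the pipeline recovers planted low-rank mixing, planted
composition groups and planted feature signal at realistic sizes and
noise.  What it does not show: robustness to platform/batch effects,
non-exponential hazards, informative censoring, correlated radiomic
noise, or marker structure weaker than the separability assumption.

## 6. Problem sizes in the test suite

Unit tests run at reduced scales (60-300 samples, 200-400 genes,
15-20-cluster aggregation) chosen so the whole suite completes in a few
minutes while every contract is still exercised; the headline checks
regenerate the full study scales (200 × 1000 deconvolution sweep, n =
236 selection/classification, 500-resample consensus).  Monte-Carlo
calibration tests (log-rank type-I error, permutation-p validity) use a
few hundred replicates and assert generous binomial bands.

## 7. Known limitations

* The corner-based estimator assumes every subclone has markers; mixtures
  with a cornerless (fully collinear) component are not identifiable.
* MDL on *exactly* noiseless data is degenerate (RSS → 0 makes the data
  term unbounded below); the numerical-floor guard handles the exact
  case, but near-machine-precision residuals between K values remain
  meaningless — real data always carries noise.
* Consensus clustering inherits k-means' spherical bias on the simplex.
* The ELM's interpolation regime (n_hidden ≫ n) makes training accuracy
  an optimistic metric by construction; held-out evaluation is exposed
  but not the default report.
* Radiomics implements a small feature subset; no resampling, filtering
  or wavelet classes.
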