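"""Convex-mixture deconvolution of bulk expression.

Bulk expression is modelled as ``X = A @ S``: each sample (row of the
samples x genes view) is a convex combination, weighted by its subclone
fractions ``A``, of ``K`` latent subclone expression profiles ``S``.
After normalising each gene's cross-sample vector to unit sum, genes lie
in a simplex whose corners are (scaled) columns of ``A``; subclone-specific
marker genes sit at those corners.  The algorithm:

1. filter and normalise genes to simplex points,
2. aggregate the point cloud with k-means,
3. pick the ``K`` cluster centres that best express all the others as
   nonnegative combinations (the corners),
4. read ``A`` off the corners and solve ``S`` by nonnegative least
   squares, optionally alternating a few refinement passes,
5. score each ``K`` with a minimum-description-length criterion and keep
   the argmin.

A fitted reference ``S`` can then be used to project new cohorts onto the
same subclones (per-sample NNLS followed by renormalisation).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.cluster import KMeans

#: expression matrices whose maximum is below this look log-transformed
LOG_SCALE_MAX = 30.0


@dataclass
class DeconvolutionResult:
    """Fitted factorisation plus the model-selection trace."""

    A: pd.DataFrame  # samples x K fractions, rows on the simplex
    S: pd.DataFrame  # K x genes reference profiles
    K: int  # MDL-argmin subclone count
    mdl_curve: dict[int, float]
    corner_clusters: dict[str, int] = field(default_factory=dict)
    markers: dict[str, list[str]] = field(default_factory=dict)
    rss: float = float("nan")


def _check_nonnegative(X: pd.DataFrame) -> None:
    if (X.to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative (linear scale)")


def preprocess_expression(
    X: pd.DataFrame,
    min_mean: float | None = None,
    top_n_by_variance: int | None = 2000,
) -> pd.DataFrame:
    """Filter genes: drop low-mean genes, keep the most variable ones.

    ``min_mean=None`` uses the 1st percentile of gene means.  Samples are
    never removed.  A warning is issued when the matrix looks
    log-transformed (max below ~30): the model expects linear scale.
    """
    _check_nonnegative(X)
    if X.to_numpy().max(initial=0.0) < LOG_SCALE_MAX:
        warnings.warn(
            "expression maximum is below 30; input may be log-scale, but the "
            "mixing model assumes linear nonnegative values",
            UserWarning,
            stacklevel=2,
        )
    means = X.mean(axis=1)
    if min_mean is None:
        min_mean = float(np.percentile(means, 1.0))
    kept = X.loc[means >= min_mean]
    if top_n_by_variance is not None and top_n_by_variance < kept.shape[0]:
        variances = kept.var(axis=1)
        top = variances.nlargest(top_n_by_variance).index
        kept = kept.loc[kept.index.intersection(top, sort=False)]
    if kept.shape[0] == 0:
        raise ValueError("all genes removed by filtering")
    return kept


def normalize_gene_vectors(X: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene's cross-sample vector to unit sum (simplex points).

    Zero-total genes cannot be placed on the simplex and are excluded
    with a warning.
    """
    _check_nonnegative(X)
    totals = X.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} zero-sum gene(s) from normalisation",
            UserWarning,
            stacklevel=2,
        )
    kept = X.loc[~zero]
    return kept.div(kept.sum(axis=1), axis=0)


def cluster_gene_vectors(
    points: pd.DataFrame,
    n_clusters: int = 50,
    seed: int = 0,
) -> tuple[pd.Series, np.ndarray]:
    """k-means aggregation of the gene simplex points.

    Returns per-gene cluster labels and the L x n_samples centre matrix
    (member means).  Deterministic under a fixed seed.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters > points.shape[0]:
        raise ValueError("n_clusters exceeds the number of genes")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(points.to_numpy())
    # recompute centres as exact member means (k-means centres already are,
    # up to convergence; this pins the contract); clusters that end up
    # empty on degenerate point sets keep the fitted centre
    pts = points.to_numpy()
    centers = np.vstack(
        [
            pts[labels == c].mean(axis=0) if (labels == c).any() else km.cluster_centers_[c]
            for c in range(n_clusters)
        ]
    )
    return pd.Series(labels, index=points.index, name="cluster"), centers


def _nnls_residual(target: np.ndarray, basis: np.ndarray) -> float:
    """Euclidean residual of nonnegative regression of target on basis columns."""
    _, resid = nnls(basis, target)
    return float(resid)


def _margin(centers: np.ndarray, subset: Sequence[int]) -> float:
    """Total NNLS residual of the non-corner centres on the corner centres."""
    basis = centers[list(subset)].T  # n_samples x K
    rest = [i for i in range(centers.shape[0]) if i not in set(subset)]
    return float(sum(_nnls_residual(centers[i], basis) for i in rest))


def find_corners(
    centers: np.ndarray,
    K: int,
    method: str = "auto",
    exhaustive_limit: int = 100_000,
) -> tuple[tuple[int, ...], float]:
    """Select the K centres that best generate the rest (simplex corners).

    The margin of a candidate corner set is the summed nonnegative-least-
    squares residual of every other centre regressed on the corners; the
    set minimising it is returned.  All C(L, K) subsets are enumerated
    when feasible (``method="auto"`` with C(L, K) <= ``exhaustive_limit``,
    or ``method="exhaustive"``); otherwise greedy forward seeding followed
    by pairwise swaps to a local optimum.
    """
    L = centers.shape[0]
    if K > L:
        raise ValueError("K exceeds the number of cluster centres")
    if K == L:
        return tuple(range(L)), 0.0
    n_subsets = math.comb(L, K)
    if method == "exhaustive" or (method == "auto" and n_subsets <= exhaustive_limit):
        best, best_margin = None, np.inf
        for subset in itertools.combinations(range(L), K):
            m = _margin(centers, subset)
            if m < best_margin:
                best, best_margin = subset, m
        return tuple(best), best_margin
    # greedy forward seeding
    chosen: list[int] = []
    for _ in range(K):
        best_i, best_m = None, np.inf
        for i in range(L):
            if i in chosen:
                continue
            m = _margin(centers, chosen + [i])
            if m < best_m:
                best_i, best_m = i, m
        chosen.append(best_i)
    current_margin = _margin(centers, chosen)
    # pairwise swaps until no improvement
    improved = True
    while improved:
        improved = False
        for pos in range(K):
            for i in range(L):
                if i in chosen:
                    continue
                trial = list(chosen)
                trial[pos] = i
                m = _margin(centers, trial)
                if m < current_margin - 1e-12:
                    chosen, current_margin = trial, m
                    improved = True
    return tuple(sorted(chosen)), current_margin


def estimate_A_S(
    X: pd.DataFrame,
    corner_centers: np.ndarray,
    refine: int = 30,
    subclone_ids: Sequence[str] | None = None,
    check_rank: bool = True,
    rtol: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Read fractions off the corners and solve the reference by NNLS.

    The initial ``A`` stacks the corner centres as columns and renormalises
    each sample row to unit sum; ``S`` is then solved gene-by-gene by
    nonnegative least squares.  ``refine`` alternating passes (re-solve
    each sample's fractions on ``S``, renormalise, re-solve ``S``) remove
    the residual contamination the finite marker dominance leaves in the
    corners; passes stop early once the relative RSS improvement falls
    below ``rtol``.  Returns ``(A, S, rss)``.

    ``check_rank=False`` skips the conditioning error; the model-order
    sweep needs this because corner sets above the true subclone number
    are necessarily rank deficient on clean data (NNLS still solves).
    """
    K = corner_centers.shape[0]
    if check_rank and np.linalg.matrix_rank(corner_centers) < K:
        raise np.linalg.LinAlgError("corner centres are rank deficient")
    Xs = X.to_numpy().T  # samples x genes
    n, g = Xs.shape
    A = corner_centers.T.copy()  # samples x K
    row_sums = A.sum(axis=1)
    if np.any(row_sums <= 0):
        raise np.linalg.LinAlgError("corner centres produce empty fraction rows")
    A = A / row_sums[:, None]

    def solve_S(Amat: np.ndarray) -> np.ndarray:
        out = np.empty((K, g))
        for j in range(g):
            out[:, j], _ = nnls(Amat, Xs[:, j])
        return out

    S = solve_S(A)
    rss = float(((Xs - A @ S) ** 2).sum())
    for _ in range(max(refine, 0)):
        basis = S.T  # genes x K
        for i in range(n):
            coef, _ = nnls(basis, Xs[i])
            total = coef.sum()
            if total > 0:
                A[i] = coef / total
        S = solve_S(A)
        new_rss = float(((Xs - A @ S) ** 2).sum())
        converged = rss - new_rss < rtol * max(new_rss, 1e-300)
        rss = new_rss
        if converged:
            break
    ids = list(subclone_ids) if subclone_ids is not None else _default_subclone_ids(K)
    A_frame = pd.DataFrame(A, index=X.columns, columns=ids)
    S_frame = pd.DataFrame(S, index=ids, columns=X.index)
    return A_frame, S_frame, rss


def _default_subclone_ids(K: int) -> list[str]:
    return [f"subclone_{k + 1}" for k in range(K)]


def mdl_value(
    rss: float, n_samples: int, n_genes: int, K: int, rss_floor: float = 0.0
) -> float:
    """BIC-flavoured minimum description length of a rank-K fit.

    MDL(K) = (n g / 2) ln(RSS / (n g)) + (P / 2) ln(n g) with
    P = n (K - 1) + K g free parameters (simplex-constrained fractions
    plus the reference profiles).  Residuals at or below ``rss_floor``
    (numerically exact fits) return -inf with a warning.
    """
    ng = n_samples * n_genes
    P = n_samples * (K - 1) + K * n_genes
    if rss <= max(rss_floor, 0.0):
        warnings.warn("zero reconstruction residual; MDL is -inf", UserWarning, stacklevel=2)
        return -np.inf
    return (ng / 2.0) * np.log(rss / ng) + (P / 2.0) * np.log(ng)


def mdl_score(X: pd.DataFrame, A: pd.DataFrame, S: pd.DataFrame) -> float:
    """MDL of a fitted factorisation of ``X`` (genes x samples)."""
    if A.shape[1] != S.shape[0]:
        raise ValueError("A and S are not conformable")
    Xs = X.to_numpy().T
    rss = float(((Xs - A.to_numpy() @ S.to_numpy()) ** 2).sum())
    n, g = Xs.shape
    return mdl_value(rss, n, g, A.shape[1])


def select_K(
    X: pd.DataFrame,
    K_min: int = 2,
    K_max: int = 8,
    n_clusters: int = 50,
    seed: int = 0,
    refine: int = 30,
    marker_quantile: float = 0.1,
) -> DeconvolutionResult:
    """Fit every K in [K_min, K_max] and keep the MDL argmin.

    Gene points are clustered once; for each K the corners are re-selected
    and the factorisation re-estimated.  MDL ties break toward smaller K
    (parsimony).  ``X`` is genes x samples and should already be filtered
    (see :func:`preprocess_expression`).
    """
    if not 2 <= K_min <= K_max <= n_clusters:
        raise ValueError("need 2 <= K_min <= K_max <= n_clusters")
    points = normalize_gene_vectors(X)
    Xn = X.loc[points.index]
    _, centers = cluster_gene_vectors(points, n_clusters=n_clusters, seed=seed)
    curve: dict[int, float] = {}
    fits: dict[int, tuple] = {}
    rss_floor = 1e-12 * float((Xn.to_numpy() ** 2).sum())  # numerically exact fit
    for K in range(K_min, K_max + 1):
        corners, _ = find_corners(centers, K)
        A, S, rss = estimate_A_S(Xn, centers[list(corners)], refine=refine, check_rank=False)
        curve[K] = mdl_value(rss, A.shape[0], S.shape[1], K, rss_floor=rss_floor)
        fits[K] = (A, S, rss, corners)
    best_K = min(curve, key=lambda k: (curve[k], k))
    A, S, rss, corners = fits[best_K]
    corner_clusters = {sub: int(c) for sub, c in zip(A.columns, corners)}
    markers = marker_genes(A, S, points, margin_quantile=marker_quantile)
    return DeconvolutionResult(
        A=A,
        S=S,
        K=best_K,
        mdl_curve=curve,
        corner_clusters=corner_clusters,
        markers=markers,
        rss=rss,
    )


def project_fractions(X_new: pd.DataFrame, S_ref: pd.DataFrame) -> pd.DataFrame:
    """Supervised projection of a new cohort onto a fixed reference.

    Gene ids are intersected (order taken from the reference); each
    sample's expression is regressed on the reference rows by NNLS and the
    coefficients renormalised to the simplex.  Samples with an all-zero
    solution are flagged in ``result.attrs["all_zero_samples"]`` and
    assigned uniform fractions.
    """
    shared = [g for g in S_ref.columns if g in set(X_new.index)]
    if not shared:
        raise ValueError("no shared gene ids between the new cohort and the reference")
    basis = S_ref[shared].to_numpy().T  # genes x K
    Xs = X_new.loc[shared].to_numpy().T  # samples x genes
    K = S_ref.shape[0]
    A = np.empty((Xs.shape[0], K))
    all_zero: list = []
    for i in range(Xs.shape[0]):
        coef, _ = nnls(basis, Xs[i])
        total = coef.sum()
        if total > 0:
            A[i] = coef / total
        else:
            all_zero.append(X_new.columns[i])
            A[i] = 1.0 / K
    if all_zero:
        warnings.warn(
            f"{len(all_zero)} sample(s) had an all-zero projection; assigned uniform fractions",
            UserWarning,
            stacklevel=2,
        )
    out = pd.DataFrame(A, index=X_new.columns, columns=S_ref.index)
    out.attrs["all_zero_samples"] = all_zero
    return out


def marker_genes(
    A: pd.DataFrame,
    S: pd.DataFrame,
    normalized_points: pd.DataFrame,
    margin_quantile: float = 0.1,
) -> dict[str, list[str]]:
    """Assign the genes nearest each simplex corner as subclone markers.

    Each gene is attributed to its nearest corner (the unit-sum-scaled
    column of ``A``); within each corner's group the nearest
    ``margin_quantile`` fraction of genes is kept.  Lists are disjoint by
    construction.
    """
    corners = A.to_numpy() / A.to_numpy().sum(axis=0, keepdims=True)  # samples x K
    pts = normalized_points.to_numpy()  # genes x samples
    d = np.linalg.norm(pts[:, None, :] - corners.T[None, :, :], axis=2)  # genes x K
    nearest = d.argmin(axis=1)
    out: dict[str, list[str]] = {}
    for k, sub in enumerate(A.columns):
        members = np.flatnonzero(nearest == k)
        n_keep = int(np.floor(margin_quantile * len(members)))
        order = members[np.argsort(d[members, k], kind="stable")]
        out[sub] = [normalized_points.index[j] for j in order[:n_keep]]
    return out


def match_subclones(
    A_est: pd.DataFrame, A_true: pd.DataFrame
) -> tuple[dict[str, str], np.ndarray]:
    """Best correlation assignment of estimated to true subclones.

    Uses Hungarian matching on the negative Pearson correlation matrix of
    fraction columns; returns the mapping (estimated id -> true id) and
    the matched per-column correlations.
    """
    from scipy.optimize import linear_sum_assignment

    est = A_est.to_numpy()
    true = A_true.loc[A_est.index].to_numpy()
    K = est.shape[1]
    corr = np.empty((K, true.shape[1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(K):
            for j in range(true.shape[1]):
                corr[i, j] = np.corrcoef(est[:, i], true[:, j])[0, 1]
    corr = np.nan_to_num(corr, nan=-1.0)  # zero-variance columns match nothing
    rows, cols = linear_sum_assignment(-corr)
    mapping = {A_est.columns[i]: A_true.columns[j] for i, j in zip(rows, cols)}
    matched = np.array([corr[i, j] for i, j in zip(rows, cols)])
    return mapping, matched
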