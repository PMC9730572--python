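"""Gene-set enrichment of subclone profiles and signature-pathway links.

Genes are ranked by subclone specificity (a subclone's share of the
gene's total reference expression), scored against gene sets with the
weighted Kolmogorov-Smirnov running sum of pre-ranked GSEA (gene-label
permutation null), summarised per sample with a rank-based pathway
score, and finally correlated with selected radiomic signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "rank_genes_for_subclone",
    "gsea_preranked",
    "sample_pathway_score",
    "correlate_signatures_pathways",
]


@dataclass
class GeneSet:
    name: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("gene set must be nonempty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene set ids must be unique")


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    p_value: float
    n_permutations: int
    running_sum: np.ndarray = field(repr=False, default=None)


def rank_genes_for_subclone(S: pd.DataFrame, k: str | int) -> pd.Series:
    """Genes ranked by specificity for subclone k.

    The score of gene j is S[k, j] / sum_k' S[k', j] — the subclone's
    share of that gene's total reference expression (1 for an exclusive
    marker, 1/K for a uniformly expressed gene).  Zero-total genes are
    excluded; ties break by gene id.
    """
    row = S.iloc[k] if isinstance(k, int) else S.loc[k]
    totals = S.sum(axis=0)
    keep = totals > 0
    score = (row[keep] / totals[keep]).astype(float)
    frame = score.rename("score").reset_index().rename(columns={"index": "gene"})
    frame = frame.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    return pd.Series(frame["score"].to_numpy(), index=frame["gene"].to_numpy(), name="score")


def _running_sum(scores: np.ndarray, is_member: np.ndarray, weight: float) -> np.ndarray:
    """Weighted KS running sum over a ranked list (descending scores)."""
    n = len(scores)
    n_hit = int(is_member.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must hit a strict subset of the ranked list")
    hit_w = np.abs(scores) ** weight
    hit_w = np.where(is_member, hit_w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member scores are 0: fall back to unweighted steps
        hit_w = is_member.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~is_member) / (n - n_hit)
    return np.cumsum(steps)


def _es_from_running(running: np.ndarray) -> float:
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_preranked(
    ranked_scores: pd.Series,
    gene_set: GeneSet | Sequence[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Pre-ranked GSEA of one gene set.

    ``ranked_scores`` maps gene id -> ranking score, ordered descending
    (it is re-sorted defensively).  The enrichment score is the extremum
    of the weighted KS running sum; the p-value comes from ``n_perm``
    random gene sets of the same size (gene-label permutation), and NES
    normalises ES by the mean magnitude of same-sign permuted scores.
    """
    genes = gene_set.gene_ids if isinstance(gene_set, GeneSet) else list(gene_set)
    ranked = ranked_scores.sort_values(ascending=False, kind="stable")
    member = ranked.index.isin(set(genes))
    if not member.any():
        raise ValueError("gene set does not overlap the ranked list")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = ranked.to_numpy(dtype=float)
    running = _running_sum(scores, member, weight)
    es = _es_from_running(running)
    rng = np.random.default_rng(seed)
    n, n_hit = len(scores), int(member.sum())
    perm_es = np.empty(n_perm)
    for p in range(n_perm):
        perm_member = np.zeros(n, dtype=bool)
        perm_member[rng.choice(n, size=n_hit, replace=False)] = True
        perm_es[p] = _es_from_running(_running_sum(scores, perm_member, weight))
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    if same_sign.size:
        p_value = float((np.abs(same_sign) >= abs(es)).mean())
        nes = float(es / np.abs(same_sign).mean())
    else:
        p_value = 1.0 / (n_perm + 1)
        nes = float(np.sign(es) * np.inf) if es != 0 else 0.0
    return EnrichmentResult(
        es=es, nes=nes, p_value=p_value, n_permutations=n_perm, running_sum=running
    )


def sample_pathway_score(X: pd.DataFrame, gene_set: GeneSet | Sequence[str]) -> pd.Series:
    """Rank-based per-sample pathway activity in [-1, 1].

    Within each sample, genes are ranked ascending by expression; the
    score is (mean rank of set genes - mean rank of the rest) scaled by
    its maximum N/2.  Being rank-based, it is invariant to any strictly
    monotone transform of a sample's expression.
    """
    genes = gene_set.gene_ids if isinstance(gene_set, GeneSet) else list(gene_set)
    member = X.index.isin(set(genes))
    if not member.any():
        raise ValueError("gene set does not overlap the expression matrix")
    if member.all():
        raise ValueError("gene set covers every gene; score is undefined")
    ranks = X.rank(axis=0, method="average")
    n = X.shape[0]
    diff = ranks[member].mean(axis=0) - ranks[~member].mean(axis=0)
    return (diff / (n / 2.0)).rename("pathway_score")


def correlate_signatures_pathways(
    feature_columns: pd.DataFrame,
    pathway_scores: pd.DataFrame,
    method: str = "spearman",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Correlate radiomic signatures with per-sample pathway scores.

    Returns (correlation, two-sided p-values, significance flags at
    ``alpha``, unadjusted) as features x pathways frames.  Sample ids
    must agree; both Spearman and Pearson are supported.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    if len(feature_columns) < 3:
        raise ValueError("correlation requires at least 3 samples")
    if not feature_columns.index.equals(pathway_scores.index):
        if set(feature_columns.index) != set(pathway_scores.index):
            raise ValueError("sample ids of features and pathway scores differ")
        pathway_scores = pathway_scores.loc[feature_columns.index]
    corr = pd.DataFrame(
        index=feature_columns.columns, columns=pathway_scores.columns, dtype=float
    )
    pvals = corr.copy()
    fn = spearmanr if method == "spearman" else pearsonr
    for f in feature_columns.columns:
        for p in pathway_scores.columns:
            r, pv = fn(feature_columns[f], pathway_scores[p])
            corr.loc[f, p] = float(r)
            pvals.loc[f, p] = float(pv)
    return corr, pvals, pvals < alpha
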