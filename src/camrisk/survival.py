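"""Risk stratification and survival statistics.

Samples are stratified by consensus clustering of their subclone fraction
rows: repeated subsampling + k-means, co-clustering frequencies
accumulated into a consensus matrix, the cluster number chosen by the PAC
statistic (proportion of ambiguous consensus entries), and final labels
from a hierarchical cut of 1 - consensus.  The two clusters are then
labelled low/high risk, and group differences are quantified with the
Kaplan-Meier estimator, the log-rank test, Cox proportional-hazards
regression (Newton iteration on the Breslow partial likelihood) and
maximally selected log-rank cutpoints for continuous markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm
from sklearn.cluster import KMeans

__all__ = [
    "ConsensusResult",
    "CoxResult",
    "CutpointResult",
    "consensus_cluster",
    "assign_risk_labels",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "optimal_cutpoint",
    "encode_covariates",
]


# ---------------------------------------------------------------------------
# consensus clustering


@dataclass
class ConsensusResult:
    consensus_matrix: pd.DataFrame  # samples x samples, for the selected K
    labels: pd.Series  # cluster id (1..K) per sample
    K_selected: int
    pac_curve: dict[int, float]


def consensus_cluster(
    A: pd.DataFrame,
    K_range: Iterable[int] = (2, 3, 4, 5, 6),
    n_reps: int = 500,
    subsample_frac: float = 0.8,
    seed: int = 0,
    K_fixed: int | None = None,
    pac_window: tuple[float, float] = (0.1, 0.9),
) -> ConsensusResult:
    """Monti-style consensus clustering of fraction rows with PAC selection.

    For each candidate K, ``n_reps`` subsamples (without replacement,
    fraction ``subsample_frac``) are clustered by k-means; co-clustering
    counts normalised by co-sampling counts give the consensus matrix.
    K is chosen to minimise PAC, the fraction of off-diagonal consensus
    entries strictly inside ``pac_window``; pass ``K_fixed`` to skip the
    selection.  Final labels come from an average-linkage cut of
    1 - consensus.  Deterministic under a fixed seed.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if not 0.0 < subsample_frac <= 1.0:
        raise ValueError("subsample_frac must lie in (0, 1]")
    K_values = [K_fixed] if K_fixed is not None else sorted(set(K_range))
    n = A.shape[0]
    if max(K_values) > n:
        raise ValueError("candidate K exceeds the sample count")
    data = A.to_numpy()
    m = max(int(round(subsample_frac * n)), max(K_values))
    rng = np.random.default_rng(seed)
    lo, hi = pac_window
    pac_curve: dict[int, float] = {}
    matrices: dict[int, np.ndarray] = {}
    for K in K_values:
        conn = np.zeros((n, n))
        both = np.zeros((n, n))
        for _ in range(n_reps):
            idx = rng.choice(n, size=m, replace=False)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            labels = KMeans(n_clusters=K, n_init=4, random_state=sub_seed).fit_predict(
                data[idx]
            )
            both[np.ix_(idx, idx)] += 1
            for c in range(K):
                members = idx[labels == c]
                conn[np.ix_(members, members)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(both > 0, conn / both, 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0
        iu = np.triu_indices(n, k=1)
        vals = consensus[iu][both[iu] > 0]
        pac_curve[K] = float(np.mean((vals > lo) & (vals < hi))) if vals.size else 0.0
        matrices[K] = consensus
    K_selected = (
        K_fixed
        if K_fixed is not None
        else min(pac_curve, key=lambda k: (pac_curve[k], k))
    )
    consensus = matrices[K_selected]
    dist = squareform(1.0 - consensus, checks=False)
    tree = linkage(dist, method="average")
    labels = fcluster(tree, t=K_selected, criterion="maxclust")
    return ConsensusResult(
        consensus_matrix=pd.DataFrame(consensus, index=A.index, columns=A.index),
        labels=pd.Series(labels, index=A.index, name="cluster"),
        K_selected=int(K_selected),
        pac_curve=pac_curve,
    )


def assign_risk_labels(
    labels: pd.Series,
    A: pd.DataFrame,
    survival: pd.DataFrame | None = None,
    adverse_subclone: str | None = None,
) -> tuple[pd.Series, dict]:
    """Name the two clusters low/high risk.

    With survival supplied, the cluster with the smaller Kaplan-Meier
    median survival is labelled high risk.  Otherwise the cluster with
    the higher mean fraction of the adverse subclone is high risk; when
    ``adverse_subclone`` is not given, the subclone whose mean fraction
    differs most between the clusters is used.  The applied rule is
    returned as metadata.
    """
    clusters = sorted(pd.Series(labels).unique())
    if len(clusters) != 2:
        raise ValueError("risk labelling requires exactly 2 clusters")
    meta: dict = {}
    high_cluster = None
    if survival is not None:
        medians = {}
        for c in clusters:
            ids = labels.index[labels == c]
            rows = survival.loc[ids]
            medians[c] = _km_median(rows["time_months"].to_numpy(), rows["event"].to_numpy())
        if medians[clusters[0]] != medians[clusters[1]]:
            high_cluster = min(clusters, key=lambda c: medians[c])
            meta["rule"] = "smaller KM median survival labelled high"
            meta["km_medians"] = {int(c): float(medians[c]) for c in clusters}
    if high_cluster is None:
        means = A.groupby(labels).mean()
        if adverse_subclone is None:
            diffs = (means.loc[clusters[0]] - means.loc[clusters[1]]).abs()
            adverse_subclone = str(diffs.idxmax())
        high_cluster = means[adverse_subclone].idxmax()
        meta["rule"] = "higher mean adverse-subclone fraction labelled high"
        meta["adverse_subclone"] = adverse_subclone
    risk = pd.Series(
        np.where(labels == high_cluster, "high", "low"), index=labels.index, name="risk"
    )
    meta["high_cluster"] = int(high_cluster)
    return risk, meta


def _km_median(times: np.ndarray, events: np.ndarray) -> float:
    km = km_estimate(times, events)
    below = km[km["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if len(below) else float("inf")


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step-function table (time, survival, at_risk, observed)
    including the t=0 row; right-continuous and nonincreasing.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(times, events)
    table = km.event_table
    surv = km.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "observed": table["observed"].to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
    return out


def _logrank_components(times, events, mask) -> tuple[float, float, float]:
    """Observed events, expectation and variance for group 1 (mask True)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    mask = np.asarray(mask, dtype=bool)
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], mask[order]
    O1 = E1 = V = 0.0
    n_at_risk = len(t)
    n1_at_risk = int(g.sum())
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            d1 = int(e[i:j][g[i:j]].sum())
            O1 += d1
            E1 += d * n1_at_risk / n_at_risk
            if n_at_risk > 1:
                V += (
                    d
                    * (n1_at_risk / n_at_risk)
                    * (1 - n1_at_risk / n_at_risk)
                    * (n_at_risk - d)
                    / (n_at_risk - 1)
                )
        n1_at_risk -= int(g[i:j].sum())
        n_at_risk -= j - i
        i = j
    return O1, E1, V


def logrank_test(times, events, group_labels) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value, 1 df).

    Invariant to relabelling the groups and to strictly monotone
    transforms of the time axis.
    """
    groups = pd.Series(group_labels)
    uniq = groups.unique()
    if len(uniq) != 2 or (groups == uniq[0]).sum() == 0 or (groups == uniq[1]).sum() == 0:
        raise ValueError("log-rank test requires exactly 2 nonempty groups")
    O1, E1, V = _logrank_components(times, events, groups.to_numpy() == uniq[0])
    if V <= 0:
        return 0.0, 1.0
    stat = (O1 - E1) ** 2 / V
    return float(stat), float(chi2_dist.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow partial likelihood, Newton iteration)


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald 95% CIs and p-values."""

    summary: pd.DataFrame  # coefficient, hazard_ratio, ci_low, ci_high, p_value
    log_likelihood: float
    n_iter: int

    def __getitem__(self, covariate: str) -> pd.Series:
        return self.summary.loc[covariate]


def breslow_loglik(X: np.ndarray, times: np.ndarray, events: np.ndarray, beta: np.ndarray) -> float:
    """Breslow partial log-likelihood only (no gradient/Hessian)."""
    order = np.argsort(times, kind="stable")
    t, e, Xo = times[order], events[order], np.asarray(X, dtype=float)[order]
    eta = np.clip(Xo @ beta, -500, 500)
    w = np.exp(eta)
    S0 = np.cumsum(w[::-1])[::-1]
    loglik = 0.0
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = e[i:j] == 1
        d = int(ev.sum())
        if d > 0:
            loglik += float(eta[i:j][ev].sum()) - d * np.log(S0[i])
        i = j
    return loglik


def _breslow_quantities(X: np.ndarray, times: np.ndarray, events: np.ndarray, beta: np.ndarray):
    """Breslow partial log-likelihood, gradient and Hessian at beta."""
    order = np.argsort(times, kind="stable")
    t, e, Xo = times[order], events[order], X[order]
    eta = Xo @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    # suffix sums over the risk sets
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xo)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * Xo[:, :, None] * Xo[:, None, :])[::-1], axis=0)[::-1]
    loglik = 0.0
    grad = np.zeros(X.shape[1])
    hess = np.zeros((X.shape[1], X.shape[1]))
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = e[i:j] == 1
        d = int(ev.sum())
        if d > 0:
            loglik += float(eta[i:j][ev].sum()) - d * np.log(S0[i])
            mu = S1[i] / S0[i]
            grad += Xo[i:j][ev].sum(axis=0) - d * mu
            hess -= d * (S2[i] / S0[i] - np.outer(mu, mu))
        i = j
    return loglik, grad, hess


def cox_fit(
    covariates: pd.DataFrame,
    times,
    events,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxResult:
    """Cox proportional-hazards fit (uni- or multivariable).

    Maximises the Breslow-tie partial likelihood by Newton iteration with
    step halving until the gradient norm falls below ``tol`` (scaled by
    1 + |log likelihood| so the criterion is meaningful at any sample
    size).  Reports the hazard ratio, Wald 95% CI and p-value per
    covariate.
    """
    X = covariates.to_numpy(dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    if np.any(X.std(axis=0) == 0):
        constant = [c for c, s in zip(covariates.columns, X.std(axis=0)) if s == 0]
        raise ValueError(f"constant covariate(s): {constant}")
    beta = np.zeros(X.shape[1])
    loglik, grad, hess = _breslow_quantities(X, times, events, beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.linalg.norm(grad) <= tol * (1.0 + abs(loglik)):
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix in Cox fit") from exc
        # step halving to guarantee ascent
        factor = 1.0
        for _ in range(30):
            candidate = beta + factor * step
            new_ll, new_grad, new_hess = _breslow_quantities(X, times, events, candidate)
            if new_ll >= loglik - 1e-12:
                break
            factor /= 2.0
        beta, loglik, grad, hess = candidate, new_ll, new_grad, new_hess
    else:
        raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")
    if np.any(np.abs(beta) > 20):
        warnings.warn(
            "very large coefficient; possible separation in the Cox model",
            UserWarning,
            stacklevel=2,
        )
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    zc = norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coefficient": beta,
            "hazard_ratio": np.exp(beta),
            "ci_low": np.exp(beta - zc * se),
            "ci_high": np.exp(beta + zc * se),
            "p_value": 2 * norm.sf(np.abs(z)),
        },
        index=covariates.columns,
    )
    return CoxResult(summary=summary, log_likelihood=float(loglik), n_iter=n_iter)


def cox_score_test(covariate, times, events) -> float:
    """Cox score chi-square at beta = 0 for a single covariate.

    For a binary covariate this is the classical identity with the
    log-rank statistic.
    """
    x = np.asarray(covariate, dtype=float).reshape(-1, 1)
    _, grad, hess = _breslow_quantities(
        x, np.asarray(times, dtype=float), np.asarray(events, dtype=int), np.zeros(1)
    )
    return float(grad[0] ** 2 / -hess[0, 0])


# ---------------------------------------------------------------------------
# maximally selected cutpoint


@dataclass
class CutpointResult:
    cutpoint: float
    statistic: float  # |standardised log-rank| at the cutpoint
    scan: pd.DataFrame = field(repr=False, default=None)  # candidate, statistic


def optimal_cutpoint(values, times, events, minprop: float = 0.1) -> CutpointResult:
    """Maximally selected log-rank split of a continuous variable.

    Candidates are the observed values whose induced split (value > cut)
    leaves at least ``minprop`` of the samples on each side; the cut
    maximising the absolute standardised log-rank statistic is returned,
    ties broken toward the lower threshold.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not 0.0 < minprop < 0.5:
        raise ValueError("minprop must lie in (0, 0.5)")
    if np.all(values == values[0]):
        raise ValueError("cutpoint requires a non-constant variable")
    n = len(values)
    min_side = minprop * n
    candidates, stats = [], []
    for cut in np.unique(values):
        mask = values > cut
        if mask.sum() < min_side or (~mask).sum() < min_side:
            continue
        O1, E1, V = _logrank_components(times, events, mask)
        z = abs(O1 - E1) / np.sqrt(V) if V > 0 else 0.0
        candidates.append(float(cut))
        stats.append(float(z))
    if not candidates:
        raise ValueError("no candidate split satisfies the minprop constraint")
    best = int(np.argmax(stats))  # argmax returns the first (lowest) maximiser
    return CutpointResult(
        cutpoint=candidates[best],
        statistic=stats[best],
        scan=pd.DataFrame({"candidate": candidates, "statistic": stats}),
    )


# ---------------------------------------------------------------------------
# covariate encoding for the clinical table


COVARIATE_CODING: Mapping[str, tuple[str, str]] = {
    # column -> (reference level, coded-1 level)
    "sex": ("F", "M"),
    "cea": ("normal", "abnormal"),
    "grade": ("low", "middle+high"),
    "stage": ("I+II", "III+IV"),
    "risk": ("low", "high"),
    "group": ("low", "high"),
}


def encode_covariates(
    clinical: pd.DataFrame, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """0/1-encode the standard clinical covariates for Cox regression.

    Unknown requested columns raise; known columns absent from the table
    are skipped with a warning (documented fallback for partial tables).
    """
    if columns is None:
        columns = [c for c in COVARIATE_CODING if c in clinical.columns]
    out = {}
    for col in columns:
        if col not in COVARIATE_CODING:
            raise ValueError(f"no coding defined for covariate {col!r}")
        if col not in clinical.columns:
            warnings.warn(
                f"covariate {col!r} missing from clinical table; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        _, one = COVARIATE_CODING[col]
        out[col] = (clinical[col] == one).astype(float)
    return pd.DataFrame(out, index=clinical.index)
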