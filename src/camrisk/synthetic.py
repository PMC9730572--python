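"""Synthetic cohorts with known ground truth.

Every downstream stage of the pipeline assumes a particular statistical
structure in its input; the generators here plant exactly that structure
so recovery can be verified:

* bulk expression as convex mixtures of ``K`` subclone profiles with
  subclone-specific marker genes (``X = A @ S`` plus noise),
* Dirichlet fraction matrices with a planted two-group prognostic
  composition difference,
* exponential survival whose hazard depends on the planted group, with
  independent uniform censoring calibrated to a target censoring rate,
* radiomic feature tables with a planted informative subset, and
* toy 3D image/mask pairs with analytic shape properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a Generator; ints are used as seeds, Generators pass through."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_ids(n: int) -> list[str]:
    return [f"s{i:04d}" for i in range(n)]


def _gene_ids(g: int) -> list[str]:
    return [f"g{j:05d}" for j in range(g)]


def _subclone_ids(k: int) -> list[str]:
    return [f"subclone_{i + 1}" for i in range(k)]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the scale of the genomic development cohort the
    pipeline targets: 200 samples, 1000 genes, 4 subclones with 30
    five-fold dominant markers each, a 161/39 low/high risk split,
    expression noise at 2% of the mean signal, 100 radiomic features of
    which 11 are informative.  Use :meth:`radiogenomic` for the matched
    imaging cohort scale (n = 236, two equal risk groups).
    """

    n_samples: int = 200
    n_genes: int = 1000
    K_true: int = 4
    markers_per_subclone: int = 30
    marker_fold: float = 5.0
    dirichlet_alpha: Sequence[Sequence[float]] = ((5.0, 5.0, 5.0, 1.0), (2.0, 2.0, 2.0, 12.0))
    group_sizes: Sequence[int] = (161, 39)
    noise_sd: float | None = None
    noise_frac: float = 0.02  # noise sd as a fraction of mean signal, if noise_sd is None
    baseline_hazard: float = 0.02  # events per month
    group_log_hr: float = 1.0
    censor_rate: float = 0.3
    n_features: int = 100
    n_informative: int = 11
    feature_effect: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must not exceed n_features")
        if sum(self.group_sizes) != self.n_samples:
            raise ValueError("group_sizes must sum to n_samples")
        if len(self.dirichlet_alpha) != len(self.group_sizes):
            raise ValueError("one alpha vector per group is required")
        for alpha in self.dirichlet_alpha:
            if len(alpha) != self.K_true:
                raise ValueError("each alpha vector must have K_true entries")
            if any(a <= 0 for a in alpha):
                raise ValueError("Dirichlet alphas must be positive")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must lie in [0, 1]")
        if self.marker_fold < 1.0:
            raise ValueError("marker_fold must be >= 1")

    @classmethod
    def radiogenomic(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Cohort at the matched imaging scale: n = 236, equal risk groups."""
        params = dict(n_samples=236, group_sizes=(118, 118), seed=seed)
        params.update(overrides)
        return cls(**params)


@dataclass
class GroundTruth:
    """Planted quantities a recovery test can compare against."""

    S_true: pd.DataFrame  # K x genes
    A_true: pd.DataFrame  # samples x K
    group_labels: pd.Series  # "low" / "high" per sample
    marker_index: Mapping[str, list[str]]  # subclone id -> marker gene ids
    informative_index: list[str] = field(default_factory=list)


def simulate_reference(
    K: int,
    n_genes: int,
    markers_per_subclone: int = 30,
    marker_fold: float = 5.0,
    seed: int | np.random.Generator = 0,
    marker_background: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Draw a K x genes subclone reference matrix with planted markers.

    Each subclone owns ``markers_per_subclone`` disjoint marker genes on
    which its expression is at least ``marker_fold`` times the maximum of
    the other subclones — the separability that makes the simplex corners
    identifiable.  ``marker_background`` scales the off-subclone expression
    of marker genes; 0 gives perfectly pure markers.

    Returns the reference matrix and the per-subclone marker gene lists.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if marker_fold < 1.0:
        raise ValueError("marker_fold must be >= 1")
    if K * markers_per_subclone > n_genes:
        raise ValueError(
            f"cannot place {K} x {markers_per_subclone} marker genes in {n_genes} genes"
        )
    rng = as_rng(seed)
    genes = _gene_ids(n_genes)
    S = rng.uniform(0.5, 4.0, size=(K, n_genes))
    order = rng.permutation(n_genes)
    marker_index: dict[str, list[str]] = {}
    for k, sub in enumerate(_subclone_ids(K)):
        cols = np.sort(order[k * markers_per_subclone : (k + 1) * markers_per_subclone])
        m = len(cols)
        if K == 1:
            # single subclone: every gene is trivially a marker of it
            marker_index[sub] = list(genes)
            continue
        others = np.arange(K) != k
        if marker_background > 0:
            back = rng.uniform(0.2, 1.0, size=(K - 1, m)) * marker_background
            owner = marker_fold * back.max(axis=0) * rng.uniform(1.0, 1.5, size=m)
        else:
            back = np.zeros((K - 1, m))
            owner = rng.uniform(2.5, 7.5, size=m)
        S[np.ix_(others, cols)] = back
        S[k, cols] = owner
        marker_index[sub] = [genes[j] for j in cols]
    return pd.DataFrame(S, index=_subclone_ids(K), columns=genes), marker_index


def simulate_fractions(
    group_sizes: Sequence[int],
    dirichlet_alpha: Sequence[Sequence[float]],
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw per-sample subclone fractions from group-specific Dirichlets.

    Returns a samples x K fraction matrix (rows on the simplex) and the
    planted group label per sample ("low"/"high" when there are two
    groups, "group_i" otherwise).
    """
    if len(group_sizes) != len(dirichlet_alpha):
        raise ValueError("one alpha vector per group is required")
    K = len(dirichlet_alpha[0])
    for alpha in dirichlet_alpha:
        if len(alpha) != K:
            raise ValueError("alpha vectors must share a common length")
        if any(a <= 0 for a in alpha):
            raise ValueError("Dirichlet alphas must be positive")
    rng = as_rng(seed)
    if len(group_sizes) == 2:
        group_names = ["low", "high"]
    else:
        group_names = [f"group_{i + 1}" for i in range(len(group_sizes))]
    rows, labels = [], []
    for name, size, alpha in zip(group_names, group_sizes, dirichlet_alpha):
        draw = rng.dirichlet(np.asarray(alpha, dtype=float), size=size)
        rows.append(draw)
        labels.extend([name] * size)
    A = np.vstack(rows)
    A = A / A.sum(axis=1, keepdims=True)
    ids = _sample_ids(A.shape[0])
    frame = pd.DataFrame(A, index=ids, columns=_subclone_ids(K))
    return frame, pd.Series(labels, index=ids, name="group")


def simulate_expression(
    A: pd.DataFrame,
    S: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    noise_model: str = "gaussian",
) -> pd.DataFrame:
    """Mix fractions and reference into a genes x samples expression matrix.

    ``gaussian`` noise is additive N(0, noise_sd) clipped at zero;
    ``lognormal`` multiplies by exp(N(0, noise_sd)).  With ``noise_sd=0``
    the result is exactly ``(A @ S).T``.
    """
    if A.shape[1] != S.shape[0]:
        raise ValueError(
            f"A has {A.shape[1]} subclone columns but S has {S.shape[0]} rows"
        )
    rng = as_rng(seed)
    X = A.to_numpy() @ S.to_numpy()  # samples x genes
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        if noise_model == "gaussian":
            X = np.clip(X + rng.normal(0.0, noise_sd, size=X.shape), 0.0, None)
        elif noise_model == "lognormal":
            X = X * np.exp(rng.normal(0.0, noise_sd, size=X.shape))
        else:
            raise ValueError(f"unknown noise_model {noise_model!r}")
    out = pd.DataFrame(X.T, index=S.columns, columns=A.index)
    out.index.name = "gene_id"
    return out


def _calibrate_censor_horizon(hazards: np.ndarray, censor_rate: float) -> float:
    """Solve for c such that uniform(0, c) censoring yields the target rate.

    For T ~ Exp(h) and C ~ U(0, c) independent,
    P(T > C) = (1 - exp(-h c)) / (h c); the mean over samples is matched.
    """
    def frac_censored(c: float) -> float:
        hc = hazards * c
        return float(np.mean((1.0 - np.exp(-hc)) / hc))

    scale = 1.0 / float(np.mean(hazards))
    lo, hi = 1e-9 * scale, 1e9 * scale
    return brentq(lambda c: frac_censored(c) - censor_rate, lo, hi, xtol=1e-12 * scale)


def simulate_survival(
    group_labels: pd.Series,
    baseline_hazard: float = 0.02,
    group_log_hr: float = 1.0,
    censor_rate: float = 0.3,
    seed: int | np.random.Generator = 0,
    covariates: bool = True,
) -> pd.DataFrame:
    """Exponential survival with a group hazard ratio and uniform censoring.

    The hazard is ``baseline_hazard * exp(group_log_hr)`` for samples
    labelled "high" and ``baseline_hazard`` otherwise.  Censoring times are
    uniform on (0, c) with c calibrated numerically so the expected
    censored fraction equals ``censor_rate``.  Clinical covariates
    (sex, CEA, grade, stage) are drawn independently of outcome.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if not 0.0 <= censor_rate <= 1.0:
        raise ValueError("censor_rate must lie in [0, 1]")
    rng = as_rng(seed)
    labels = pd.Series(group_labels)
    n = len(labels)
    hazards = baseline_hazard * np.exp(group_log_hr * (labels.to_numpy() == "high"))
    T = rng.exponential(1.0 / hazards)
    if censor_rate == 0.0:
        time, event = T, np.ones(n, dtype=int)
    elif censor_rate == 1.0:
        C = rng.uniform(0.0, 1e-6 / baseline_hazard, size=n)
        time, event = C, np.zeros(n, dtype=int)
    else:
        c = _calibrate_censor_horizon(hazards, censor_rate)
        C = rng.uniform(0.0, c, size=n)
        event = (T <= C).astype(int)
        time = np.minimum(T, C)
    time = np.maximum(time, 1e-9)
    frame = pd.DataFrame({"time_months": time, "event": event}, index=labels.index)
    frame.index.name = "sample_id"
    if covariates:
        frame["sex"] = rng.choice(["M", "F"], size=n)
        frame["cea"] = rng.choice(["normal", "abnormal"], size=n, p=[0.7, 0.3])
        frame["grade"] = rng.choice(["low", "middle+high"], size=n)
        frame["stage"] = rng.choice(["I+II", "III+IV"], size=n)
    frame["group"] = labels.to_numpy()
    return frame


def simulate_radiomic_features(
    group_labels: pd.Series,
    n_features: int = 100,
    n_informative: int = 11,
    feature_effect: float = 1.5,
    seed: int | np.random.Generator = 0,
    fraction_values: pd.Series | None = None,
    fraction_effect: float = 0.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Standard-normal feature table with a planted informative subset.

    Informative columns are shifted by ``feature_effect`` for samples in
    the "high" group; optionally they are additionally tied linearly to a
    supplied subclone-fraction column (z-scored) with slope
    ``fraction_effect``.  Column names are stable and unique.
    """
    if n_informative > n_features:
        raise ValueError("n_informative must not exceed n_features")
    rng = as_rng(seed)
    labels = pd.Series(group_labels)
    n = len(labels)
    Z = rng.standard_normal((n, n_features))
    informative = np.sort(rng.choice(n_features, size=n_informative, replace=False))
    shift = feature_effect * (labels.to_numpy() == "high").astype(float)
    if fraction_values is not None and fraction_effect != 0.0:
        frac = pd.Series(fraction_values).reindex(labels.index).to_numpy(dtype=float)
        frac = (frac - frac.mean()) / (frac.std() if frac.std() > 0 else 1.0)
        shift = shift + fraction_effect * frac
    Z[:, informative] += shift[:, None]
    names = [f"radiomic_{i:03d}" for i in range(n_features)]
    frame = pd.DataFrame(Z, index=labels.index, columns=names)
    frame.index.name = "sample_id"
    return frame, [names[i] for i in informative]


def simulate_image(
    shape_spec: Mapping | None = None,
    intensity_spec: Mapping | None = None,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Toy 3D image and binary mask with an analytic shape.

    ``shape_spec`` keys: ``kind`` ("sphere", "ellipsoid" or "box"),
    ``grid`` (array shape), ``center`` (physical, defaults to the grid
    centre) and size parameters (``radius``, ``semiaxes`` or
    ``half_sizes``, in physical units).  ``intensity_spec`` keys:
    ``background``, ``foreground``, ``texture_sd`` (additive noise inside
    the mask).
    """
    shape_spec = dict(shape_spec or {})
    intensity_spec = dict(intensity_spec or {})
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    rng = as_rng(seed)
    kind = shape_spec.get("kind", "sphere")
    grid = tuple(shape_spec.get("grid", (32, 32, 32)))
    idx = np.indices(grid).astype(float)
    center = shape_spec.get("center")
    if center is None:
        center = [(g - 1) / 2.0 * s for g, s in zip(grid, spacing)]
    phys = [idx[a] * spacing[a] - center[a] for a in range(3)]
    if kind == "sphere":
        r = float(shape_spec.get("radius", 8.0))
        mask = phys[0] ** 2 + phys[1] ** 2 + phys[2] ** 2 <= r**2
    elif kind == "ellipsoid":
        ax = np.asarray(shape_spec.get("semiaxes", (8.0, 6.0, 4.0)), dtype=float)
        mask = sum((phys[a] / ax[a]) ** 2 for a in range(3)) <= 1.0
    elif kind == "box":
        hs = np.asarray(shape_spec.get("half_sizes", (8.0, 6.0, 4.0)), dtype=float)
        mask = np.all([np.abs(phys[a]) <= hs[a] for a in range(3)], axis=0)
    else:
        raise ValueError(f"unknown shape kind {kind!r}")
    if not mask.any():
        raise ValueError("empty mask: shape does not intersect the grid")
    background = float(intensity_spec.get("background", 0.0))
    foreground = float(intensity_spec.get("foreground", 100.0))
    texture_sd = float(intensity_spec.get("texture_sd", 0.0))
    image = np.full(grid, background, dtype=float)
    image[mask] = foreground
    if texture_sd > 0:
        image[mask] += rng.normal(0.0, texture_sd, size=int(mask.sum()))
    return image, mask.astype(np.uint8)


@dataclass
class SyntheticCohort:
    """Bundle of generated cohort tables plus the planted ground truth."""

    expression: pd.DataFrame  # genes x samples
    clinical: pd.DataFrame  # samples x (time_months, event, covariates, group)
    features: pd.DataFrame  # samples x radiomic features
    truth: GroundTruth


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort (expression, clinical, features) from one config."""
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(5)]
    S, markers = simulate_reference(
        config.K_true,
        config.n_genes,
        config.markers_per_subclone,
        config.marker_fold,
        seed=rngs[0],
    )
    A, labels = simulate_fractions(config.group_sizes, config.dirichlet_alpha, seed=rngs[1])
    if config.noise_sd is not None:
        noise_sd = config.noise_sd
    else:
        noise_sd = config.noise_frac * float((A.to_numpy() @ S.to_numpy()).mean())
    X = simulate_expression(A, S, noise_sd=noise_sd, seed=rngs[2])
    clinical = simulate_survival(
        labels,
        baseline_hazard=config.baseline_hazard,
        group_log_hr=config.group_log_hr,
        censor_rate=config.censor_rate,
        seed=rngs[3],
    )
    features, informative = simulate_radiomic_features(
        labels,
        n_features=config.n_features,
        n_informative=config.n_informative,
        feature_effect=config.feature_effect,
        seed=rngs[4],
    )
    truth = GroundTruth(
        S_true=S,
        A_true=A,
        group_labels=labels,
        marker_index=markers,
        informative_index=informative,
    )
    return SyntheticCohort(expression=X, clinical=clinical, features=features, truth=truth)
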