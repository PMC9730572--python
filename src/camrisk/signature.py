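"""Prognostic signature selection and the imaging risk classifier.

Feature selection is L1-penalised Cox regression over a log-spaced
penalty grid with seeded k-fold cross-validation of the partial-
likelihood deviance; the penalty is chosen by the minimum-deviance or the
one-standard-error rule and the nonzero-coefficient features form the
signature.  The classifier is an extreme learning machine: a single
hidden layer with fixed random weights, output weights solved in closed
form by a ridge-stabilised pseudoinverse against one-hot targets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .survival import breslow_loglik, cox_fit

__all__ = [
    "Standardization",
    "SelectionResult",
    "ELMModel",
    "standardize",
    "lasso_cox_select",
    "elm_train",
    "elm_predict",
    "evaluate_classifier",
]


# ---------------------------------------------------------------------------
# standardisation


@dataclass
class Standardization:
    """Per-feature z-scoring transform learned on training data."""

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in table.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing}")
        X = table[self.columns].to_numpy(dtype=float)
        return pd.DataFrame(
            (X - self.means) / self.sds, index=table.index, columns=self.columns
        )


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, Standardization]:
    """z-score each column; constant columns are dropped with a warning."""
    if table.shape[0] < 2:
        raise ValueError("standardisation requires at least 2 samples")
    means = table.mean(axis=0)
    sds = table.std(axis=0, ddof=0)
    constant = sds.index[sds == 0].tolist()
    if len(constant) == table.shape[1]:
        raise ValueError("all feature columns are constant")
    if constant:
        warnings.warn(f"dropping constant column(s): {constant}", UserWarning, stacklevel=2)
    kept = [c for c in table.columns if c not in constant]
    tf = Standardization(
        columns=kept,
        means=means[kept].to_numpy(),
        sds=sds[kept].to_numpy(),
        dropped=constant,
    )
    return tf.apply(table), tf


# ---------------------------------------------------------------------------
# LASSO-Cox selection


@dataclass
class SelectionResult:
    selected_features: list[str]  # ordered by |coefficient|, descending
    coefficients: pd.Series  # nonzero coefficients of the selected features
    lambda_grid: np.ndarray
    cv_curve: pd.DataFrame  # lambda, mean deviance, se
    lambda_chosen: float
    rule: str


_partial_loglik = breslow_loglik


def _coxnet_path(X: np.ndarray, y, alphas: np.ndarray | None, n_lambdas: int):
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        alphas=alphas,
        n_alphas=n_lambdas,
        alpha_min_ratio=0.01,
        fit_baseline_model=False,
        max_iter=200_000,
        tol=1e-7,
    )
    model.fit(X, y)
    return np.asarray(model.alphas_), np.asarray(model.coef_)  # coef_: d x n_alphas


def lasso_cox_select(
    features: pd.DataFrame,
    times,
    events,
    n_folds: int = 10,
    rule: str = "1se",
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_grid: Sequence[float] | None = None,
) -> SelectionResult:
    """Cross-validated L1-penalised Cox feature selection.

    Features are z-scored internally; coefficients are reported on the
    standardised scale (selection is invariant to that choice).  Folds
    are stratified on the event indicator so every fold contains events.
    ``rule`` is "min" (deviance minimiser) or "1se".  A grid value of 0
    is fitted unpenalised.
    """
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if events.sum() < n_folds:
        raise ValueError("need at least one event per fold")
    from sksurv.util import Surv

    Z, tf = standardize(features)
    X = Z.to_numpy()
    y = Surv.from_arrays(event=events.astype(bool), time=times)

    if lambda_grid is not None:
        grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    else:
        grid, _ = _coxnet_path(X, y, None, n_lambdas)

    def fit_at(Xm, ym, tm, em, alphas):
        """Coefficient matrix (d x len(alphas)) on a subset; alpha 0 unpenalised."""
        pos = alphas[alphas > 0]
        coefs = np.zeros((Xm.shape[1], len(alphas)))
        if pos.size:
            fitted_alphas, path_coefs = _coxnet_path(Xm, ym, pos, n_lambdas)
            # coxnet may terminate the path early; use the nearest fitted
            # penalty for any requested value it skipped
            for i, a in enumerate(alphas):
                if a > 0:
                    j = int(np.argmin(np.abs(np.log(fitted_alphas) - np.log(a))))
                    coefs[:, i] = path_coefs[:, j]
        for idx in np.flatnonzero(alphas == 0):
            frame = pd.DataFrame(Xm, columns=tf.columns)
            res = cox_fit(frame, tm, em)
            coefs[:, idx] = res.summary["coefficient"].to_numpy()
        return coefs

    folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    deviances = np.zeros((n_folds, len(grid)))
    for f, (train, test) in enumerate(folds.split(X, events)):
        if events[train].sum() == 0 or events[test].sum() == 0:
            warnings.warn("fold without events; refolding", UserWarning, stacklevel=2)
            folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + 1)
            return lasso_cox_select(
                features, times, events, n_folds, rule, seed + 1, n_lambdas, lambda_grid
            )
        ytr = Surv.from_arrays(event=events[train].astype(bool), time=times[train])
        coefs = fit_at(X[train], ytr, times[train], events[train], grid)
        for a in range(len(grid)):
            beta = coefs[:, a]
            # glmnet-style CV deviance: full-data minus training partial likelihood
            dev = -2.0 * (
                _partial_loglik(X, times, events, beta)
                - _partial_loglik(X[train], times[train], events[train], beta)
            )
            deviances[f, a] = dev
    mean_dev = deviances.mean(axis=0)
    se_dev = deviances.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(mean_dev))
    if rule == "min":
        i_chosen = i_min
    else:
        threshold = mean_dev[i_min] + se_dev[i_min]
        within = np.flatnonzero(mean_dev <= threshold)
        i_chosen = int(within[np.argmax(grid[within])])  # sparsest within 1 se
    lambda_chosen = float(grid[i_chosen])

    full_coefs = fit_at(X, y, times, events, grid)
    beta = full_coefs[:, i_chosen]
    nonzero = np.flatnonzero(beta != 0)
    order = nonzero[np.argsort(-np.abs(beta[nonzero]), kind="stable")]
    selected = [tf.columns[j] for j in order]
    return SelectionResult(
        selected_features=selected,
        coefficients=pd.Series(beta[order], index=selected, name="coefficient"),
        lambda_grid=grid,
        cv_curve=pd.DataFrame({"lambda": grid, "mean_deviance": mean_dev, "se": se_dev}),
        lambda_chosen=lambda_chosen,
        rule=rule,
    )


# ---------------------------------------------------------------------------
# extreme learning machine


@dataclass
class ELMModel:
    """Single-hidden-layer classifier with random fixed hidden weights."""

    input_features: list[str]
    n_hidden: int
    hidden_weights: np.ndarray  # n_hidden x d
    hidden_bias: np.ndarray  # n_hidden
    output_weights: np.ndarray  # n_hidden x n_classes
    activation: str
    seed: int
    standardization: Standardization
    classes: list[str]

    def to_json(self) -> str:
        payload = {
            "input_features": self.input_features,
            "n_hidden": self.n_hidden,
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_bias": self.hidden_bias.tolist(),
            "output_weights": self.output_weights.tolist(),
            "activation": self.activation,
            "seed": self.seed,
            "classes": self.classes,
            "standardization": {
                "columns": self.standardization.columns,
                "means": self.standardization.means.tolist(),
                "sds": self.standardization.sds.tolist(),
                "dropped": self.standardization.dropped,
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ELMModel":
        d = json.loads(text)
        tf = Standardization(
            columns=d["standardization"]["columns"],
            means=np.asarray(d["standardization"]["means"]),
            sds=np.asarray(d["standardization"]["sds"]),
            dropped=d["standardization"]["dropped"],
        )
        return cls(
            input_features=d["input_features"],
            n_hidden=d["n_hidden"],
            hidden_weights=np.asarray(d["hidden_weights"]),
            hidden_bias=np.asarray(d["hidden_bias"]),
            output_weights=np.asarray(d["output_weights"]),
            activation=d["activation"],
            seed=d["seed"],
            standardization=tf,
            classes=d["classes"],
        )


def _activate(Z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-Z))
    if activation == "tanh":
        return np.tanh(Z)
    raise ValueError(f"unknown activation {activation!r}")


def elm_train(
    features: pd.DataFrame,
    labels,
    n_hidden: int = 1000,
    activation: str = "sigmoid",
    seed: int = 0,
    stabilizer: float = 1e-8,
) -> ELMModel:
    """Fit an extreme learning machine to class labels.

    Hidden weights and biases are drawn once from a seeded standard
    normal; output weights solve the ridge-stabilised least-squares
    problem H beta = T with one-hot targets T.  The per-feature
    standardisation is stored in the model for reuse at prediction.
    """
    labels = pd.Series(labels, index=features.index)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    Z, tf = standardize(features)
    X = Z.to_numpy()
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n_hidden, X.shape[1]))
    b = rng.standard_normal(n_hidden)
    H = _activate(X @ W.T + b, activation)
    T = np.zeros((X.shape[0], len(classes)))
    for j, c in enumerate(classes):
        T[labels.to_numpy() == c, j] = 1.0
    gram = H.T @ H + stabilizer * np.eye(n_hidden)
    beta = np.linalg.solve(gram, H.T @ T)
    return ELMModel(
        input_features=tf.columns,
        n_hidden=n_hidden,
        hidden_weights=W,
        hidden_bias=b,
        output_weights=beta,
        activation=activation,
        seed=seed,
        standardization=tf,
        classes=[str(c) for c in classes],
    )


def elm_predict(model: ELMModel, features: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Predicted class labels and per-class scores for new samples.

    Columns are aligned by name (order-insensitive); a missing feature
    column raises.
    """
    Z = model.standardization.apply(features)
    H = _activate(Z.to_numpy() @ model.hidden_weights.T + model.hidden_bias, model.activation)
    scores = H @ model.output_weights
    labels = pd.Series(
        [model.classes[i] for i in scores.argmax(axis=1)],
        index=features.index,
        name="predicted",
    )
    score_frame = pd.DataFrame(scores, index=features.index, columns=model.classes)
    return labels, score_frame


def evaluate_classifier(predicted, truth) -> dict:
    """Overall and per-class accuracy with confusion counts."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.size == 0:
        raise ValueError("empty input")
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth lengths differ")
    classes = sorted(set(truth) | set(predicted))
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for p, t in zip(predicted, truth):
        confusion.loc[t, p] += 1
    per_class = {}
    for c in classes:
        total = int((truth == c).sum())
        if total:
            per_class[c] = float(((truth == c) & (predicted == truth)).sum() / total)
    return {
        "accuracy": float((predicted == truth).mean()),
        "per_class_accuracy": per_class,
        "confusion": confusion,
    }
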