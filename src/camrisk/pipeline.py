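"""End-to-end orchestration of the three analysis steps.

Step 1 (genomic): deconvolve bulk expression into subclone fractions,
select the subclone number by MDL, stratify samples into consensus risk
groups and report survival statistics.  Step 2 (radiogenomic): project a
matched cohort onto the fitted reference, re-derive risk groups, select
prognostic radiomic features by LASSO-Cox and train the ELM classifier.
Step 3 (validation): predict risk from imaging features alone and test
the split against observed survival.

Every stage can persist its artifacts (CSV/JSON) together with a
manifest recording input hashes, settings and seeds; an existing
manifest is never silently overwritten (pass ``force=True``).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as io_mod
from .deconvolution import (
    DeconvolutionResult,
    preprocess_expression,
    project_fractions,
    select_K,
)
from .signature import (
    ELMModel,
    SelectionResult,
    elm_predict,
    elm_train,
    evaluate_classifier,
    lasso_cox_select,
)
from .survival import (
    assign_risk_labels,
    consensus_cluster,
    cox_fit,
    encode_covariates,
    km_estimate,
    logrank_test,
)

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""


@dataclass
class DeconvolutionSettings:
    k_min: int = 2
    k_max: int = 8
    n_clusters: int = 50
    seed: int = 0
    min_mean: float | None = None
    top_n_by_variance: int | None = 2000


@dataclass
class ConsensusSettings:
    k_range: Sequence[int] = (2, 3, 4, 5, 6)
    n_reps: int = 500
    subsample_frac: float = 0.8
    seed: int = 0
    K_fixed: int | None = None


@dataclass
class SelectionSettings:
    n_folds: int = 10
    rule: str = "1se"
    seed: int = 0


@dataclass
class ELMSettings:
    n_hidden: int = 1000
    activation: str = "sigmoid"
    seed: int = 0


@dataclass
class PipelineConfig:
    expression_path: str | None = None
    clinical_path: str | None = None
    features_path: str | None = None
    outdir: str | None = None
    deconvolution: DeconvolutionSettings = field(default_factory=DeconvolutionSettings)
    consensus: ConsensusSettings = field(default_factory=ConsensusSettings)
    selection: SelectionSettings = field(default_factory=SelectionSettings)
    elm: ELMSettings = field(default_factory=ELMSettings)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(
    outdir: Path, stage: str, inputs: dict, settings: dict, force: bool
) -> None:
    manifest_path = outdir / f"{stage}_manifest.json"
    if manifest_path.exists() and not force:
        raise PipelineError(
            f"[{stage}] manifest {manifest_path} exists; pass force=True to recompute"
        )
    manifest = {
        "stage": stage,
        "version": __version__,
        "inputs": {k: (_sha256(v) if v else None) for k, v in inputs.items()},
        "settings": settings,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))


def _load(config: PipelineConfig, attr: str, value, reader, stage: str):
    if value is not None:
        return value
    path = getattr(config, attr)
    if path is None:
        raise PipelineError(f"[{stage}] no {attr.replace('_path', '')} input provided")
    if not Path(path).exists():
        raise PipelineError(f"[{stage}] input file not found: {path}")
    return reader(path)


def _survival_report(risk: pd.Series, clinical: pd.DataFrame) -> dict:
    """Log-rank + uni/multivariable Cox of the risk split, KM per group."""
    times = clinical["time_months"].to_numpy()
    events = clinical["event"].to_numpy()
    report: dict = {}
    if risk.nunique() == 2:
        chi2, p = logrank_test(times, events, risk)
        report["logrank"] = {"chi_square": chi2, "p_value": p}
        risk_cov = pd.DataFrame({"risk": (risk == "high").astype(float)}, index=risk.index)
        uni = cox_fit(risk_cov, times, events)
        report["cox_univariable"] = uni.summary.loc["risk"].to_dict()
        covs = encode_covariates(clinical, columns=["sex", "cea", "grade", "stage"])
        multi_design = pd.concat([risk_cov, covs], axis=1)
        multi_design = multi_design.loc[:, multi_design.std(axis=0) > 0]
        multi = cox_fit(multi_design, times, events)
        report["cox_multivariable"] = {
            cov: multi.summary.loc[cov].to_dict() for cov in multi.summary.index
        }
    else:
        warnings.warn("risk split is degenerate; survival report limited", UserWarning)
    report["km"] = {
        str(g): km_estimate(
            clinical.loc[risk == g, "time_months"], clinical.loc[risk == g, "event"]
        ).to_dict(orient="list")
        for g in risk.unique()
    }
    return report


@dataclass
class GenomicStepResult:
    deconvolution: DeconvolutionResult
    risk_labels: pd.Series
    risk_meta: dict
    survival_report: dict


def run_genomic_step(
    config: PipelineConfig,
    expression: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
    force: bool = False,
) -> GenomicStepResult:
    """Deconvolution + consensus risk stratification + survival report."""
    stage = "genomic"
    X = _load(config, "expression_path", expression, io_mod.read_expression_tsv, stage)
    clin = _load(config, "clinical_path", clinical, io_mod.read_clinical_csv, stage)
    missing = [s for s in X.columns if s not in clin.index]
    if missing:
        raise PipelineError(f"[{stage}] samples missing from clinical table: {missing[:5]}")
    clin = clin.loc[X.columns]
    d = config.deconvolution
    Xf = preprocess_expression(X, min_mean=d.min_mean, top_n_by_variance=d.top_n_by_variance)
    deconv = select_K(
        Xf, K_min=d.k_min, K_max=d.k_max, n_clusters=d.n_clusters, seed=d.seed
    )
    c = config.consensus
    cons = consensus_cluster(
        deconv.A,
        K_range=c.k_range,
        n_reps=c.n_reps,
        subsample_frac=c.subsample_frac,
        seed=c.seed,
        K_fixed=c.K_fixed,
    )
    if cons.K_selected != 2:
        raise PipelineError(
            f"[{stage}] consensus clustering selected {cons.K_selected} groups; "
            "risk labelling requires 2 (fix with ConsensusSettings.K_fixed=2)"
        )
    risk, meta = assign_risk_labels(cons.labels, deconv.A, survival=clin)
    report = _survival_report(risk, clin)
    result = GenomicStepResult(
        deconvolution=deconv, risk_labels=risk, risk_meta=meta, survival_report=report
    )
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_manifest(
            outdir,
            stage,
            {"expression": config.expression_path, "clinical": config.clinical_path},
            {"deconvolution": asdict(d), "consensus": asdict(c)},
            force,
        )
        io_mod.write_fractions_csv(deconv.A, outdir / "fractions.csv")
        io_mod.write_reference_csv(deconv.S, outdir / "reference.csv")
        risk.to_frame().assign(cluster=cons.labels).to_csv(
            outdir / "risk_labels.csv", index_label="sample_id"
        )
        (outdir / "genomic_result.json").write_text(
            json.dumps(
                {
                    "K": deconv.K,
                    "mdl_curve": deconv.mdl_curve,
                    "rss": deconv.rss,
                    "pac_curve": cons.pac_curve,
                    "risk_rule": meta,
                    "survival_report": {
                        k: v for k, v in report.items() if k != "km"
                    },
                },
                indent=2,
                default=str,
            )
        )
    return result


@dataclass
class RadiogenomicStepResult:
    fractions: pd.DataFrame
    risk_labels: pd.Series
    selection: SelectionResult
    model: ELMModel
    training_report: dict


def run_radiogenomic_step(
    config: PipelineConfig,
    reference: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
    features: pd.DataFrame | None = None,
    risk_labels: pd.Series | None = None,
    force: bool = False,
) -> RadiogenomicStepResult:
    """Reference-supervised projection, risk groups, LASSO-Cox + ELM."""
    stage = "radiogenomic"
    X = _load(config, "expression_path", expression, io_mod.read_expression_tsv, stage)
    clin = _load(config, "clinical_path", clinical, io_mod.read_clinical_csv, stage)
    feats = _load(config, "features_path", features, io_mod.read_features_csv, stage)
    if not set(X.columns) <= set(clin.index) or not set(X.columns) <= set(feats.index):
        raise PipelineError(f"[{stage}] sample ids of expression/clinical/features differ")
    clin = clin.loc[X.columns]
    feats = feats.loc[X.columns]
    A = project_fractions(X, reference)
    if risk_labels is None:
        c = config.consensus
        cons = consensus_cluster(
            A,
            K_range=c.k_range,
            n_reps=c.n_reps,
            subsample_frac=c.subsample_frac,
            seed=c.seed,
            K_fixed=c.K_fixed,
        )
        if cons.K_selected != 2:
            raise PipelineError(
                f"[{stage}] consensus clustering selected {cons.K_selected} groups"
            )
        risk_labels, _ = assign_risk_labels(cons.labels, A, survival=clin)
    risk_labels = risk_labels.loc[feats.index]
    s = config.selection
    selection = lasso_cox_select(
        feats,
        clin["time_months"].to_numpy(),
        clin["event"].to_numpy(),
        n_folds=s.n_folds,
        rule=s.rule,
        seed=s.seed,
    )
    if not selection.selected_features:
        raise PipelineError(
            f"[{stage}] LASSO-Cox selected no features (penalty too strong); "
            "no signature can be trained"
        )
    e = config.elm
    model = elm_train(
        feats[selection.selected_features],
        risk_labels,
        n_hidden=e.n_hidden,
        activation=e.activation,
        seed=e.seed,
    )
    predicted, _ = elm_predict(model, feats[selection.selected_features])
    training_report = evaluate_classifier(predicted.to_numpy(), risk_labels.to_numpy())
    training_report = {
        "accuracy": training_report["accuracy"],
        "per_class_accuracy": training_report["per_class_accuracy"],
    }
    result = RadiogenomicStepResult(
        fractions=A,
        risk_labels=risk_labels,
        selection=selection,
        model=model,
        training_report=training_report,
    )
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_manifest(
            outdir,
            stage,
            {
                "expression": config.expression_path,
                "clinical": config.clinical_path,
                "features": config.features_path,
            },
            {"selection": asdict(s), "elm": asdict(e)},
            force,
        )
        io_mod.write_fractions_csv(A, outdir / "projected_fractions.csv")
        selection.coefficients.to_frame().assign(
            lambda_chosen=selection.lambda_chosen
        ).to_csv(outdir / "selection.csv", index_label="feature")
        (outdir / "elm_model.json").write_text(model.to_json())
        (outdir / "radiogenomic_result.json").write_text(
            json.dumps(
                {
                    "selected_features": selection.selected_features,
                    "lambda_chosen": selection.lambda_chosen,
                    "rule": selection.rule,
                    "training_report": training_report,
                },
                indent=2,
            )
        )
    return result


@dataclass
class ValidationStepResult:
    predicted_risk: pd.Series
    survival_report: dict


def run_validation_step(
    config: PipelineConfig,
    model: ELMModel,
    features: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
    force: bool = False,
) -> ValidationStepResult:
    """Imaging-only risk prediction and survival assessment."""
    stage = "validation"
    feats = _load(config, "features_path", features, io_mod.read_features_csv, stage)
    clin = _load(config, "clinical_path", clinical, io_mod.read_clinical_csv, stage)
    if not set(feats.index) <= set(clin.index):
        raise PipelineError(f"[{stage}] feature samples missing from clinical table")
    clin = clin.loc[feats.index]
    missing = [c for c in model.input_features if c not in feats.columns]
    if missing:
        raise PipelineError(f"[{stage}] missing selected feature column(s): {missing}")
    predicted, _ = elm_predict(model, feats)
    report = _survival_report(
        pd.Series(predicted, index=feats.index, name="risk"), clin
    )
    result = ValidationStepResult(predicted_risk=predicted, survival_report=report)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_manifest(
            outdir,
            stage,
            {"features": config.features_path, "clinical": config.clinical_path},
            {"elm": {"n_hidden": model.n_hidden, "seed": model.seed}},
            force,
        )
        predicted.to_frame().to_csv(outdir / "predicted_risk.csv", index_label="sample_id")
        (outdir / "validation_result.json").write_text(
            json.dumps(
                {k: v for k, v in report.items() if k != "km"}, indent=2, default=str
            )
        )
    return result
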