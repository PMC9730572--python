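# camrisk

Radiogenomic risk stratification of bulk tumour expression: deconvolve
mixed expression into latent subclones, stratify patients into prognostic
risk groups from their subclone composition, and learn to predict those
genomically defined groups from CT radiomic features alone.

## Who this is for

Researchers studying intratumour heterogeneity (ITH) in bulk
transcriptomic cohorts — colorectal cancer being the motivating setting —
who want a tested, reproducible implementation of the three-step
analysis:

1. **Genomic step.** Bulk expression is modelled as a convex mixture
   `X = A·S`: each sample's expression (row of the samples × genes view)
   is a weighted average of `K` subclone profiles (`S`, K × genes), with
   weights `A` (samples × K) on the probability simplex.  After scaling
   each gene's cross-sample vector to unit sum, genes populate a simplex
   whose corners are the columns of `A`; subclone-specific marker genes
   sit at the corners.  The pipeline clusters gene vectors, finds the
   corner set by nonnegative-least-squares margin minimisation, reads
   `A` off the corners, solves `S` by NNLS, and selects `K` with a
   minimum-description-length (MDL) criterion
   `MDL(K) = (ng/2)·ln(RSS/ng) + (P/2)·ln(ng)`, `P = n(K−1) + Kg`.
2. **Stratification.** Consensus clustering (repeated subsampling +
   k-means, PAC model selection) of the fraction matrix splits patients
   into two risk groups; Kaplan–Meier curves, the log-rank test, Cox
   proportional-hazards regression and maximally selected cutpoints
   quantify the prognostic separation.  New cohorts are projected onto a
   fixed reference `S` by per-sample NNLS.
3. **Radiogenomic bridge.** Cross-validated LASSO-Cox selects prognostic
   radiomic features; an extreme learning machine (1000 random hidden
   nodes, pseudoinverse output weights) predicts the risk group from the
   selected imaging features, so risk can be assessed without expression
   data.  A compact radiomics module computes the named shape
   (surface/volume ratio), GLDM (dependence entropy) and first-order
   features from NIfTI image/mask pairs.

A fully ground-truthed synthetic-data module generates expression
mixtures, fraction matrices, survival times, radiomic tables and toy 3D
images so every stage is testable end to end without access data.

## Worked example

Generate a 200-sample × 1000-gene synthetic cohort with four planted
subclones and run all three steps:

```bash
camrisk simulate demo --n-samples 200 --n-genes 1000 --k-true 4 --seed 11
camrisk run-all demo_run \
  --expression demo/expression.tsv --clinical demo/clinical.csv \
  --rg-expression demo/expression.tsv --rg-clinical demo/clinical.csv \
  --rg-features demo/features.csv --rule min --seed 11
```

prints

```json
{
  "K": 4,
  "genomic_logrank_p": 5.095852724067478e-07,
  "selected_features": ["radiomic_033", "radiomic_032", "radiomic_048"],
  "training_accuracy": 1.0,
  "validation_logrank_p": 5.095852724067478e-07
}
```

Reading this: MDL recovered the planted subclone number (`K = 4`); the
consensus risk groups derived from the subclone fractions separate
overall survival strongly (log-rank p ≈ 5·10⁻⁷); LASSO-Cox kept three
planted radiomic features, and the ELM trained on them reproduces the
genomic risk labels perfectly on the training cohort; applying the
imaging-only classifier yields the same prognostic split.  Artifacts
(fraction/reference matrices, MDL curve, consensus labels, Cox tables,
the serialized ELM, per-stage manifests with input hashes and seeds) are
written under `demo_run/`.

The same operations are available as library functions
(`camrisk.select_K`, `camrisk.consensus_cluster`, `camrisk.cox_fit`,
`camrisk.lasso_cox_select`, `camrisk.elm_train`, …); see
`docs/methods.md` for the underlying models and the numerical choices.

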