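"""Readers and writers for the pipeline's plain-text formats.

Expression travels as TSV with genes in rows and a header of sample ids;
clinical, fraction and feature tables as CSV keyed by ``sample_id``;
gene sets as GMT; images as NIfTI.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSet

CLINICAL_REQUIRED = ("time_months", "event")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples expression matrix from TSV (gene ids in column 0)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates or frame.columns.has_duplicates:
        raise ValueError(f"duplicate gene or sample ids in {path}")
    return frame


def write_expression_tsv(X: pd.DataFrame, path: str | Path) -> None:
    X.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    """Clinical/survival table keyed by sample_id; strict required columns."""
    frame = pd.read_csv(path, index_col="sample_id")
    missing = [c for c in CLINICAL_REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"clinical table {path} lacks required column(s): {missing}")
    if frame.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    if (frame["time_months"] <= 0).any():
        raise ValueError("time_months must be positive")
    if not frame["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return frame


def write_clinical_csv(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, index_label="sample_id")


def read_features_csv(path: str | Path) -> pd.DataFrame:
    """Samples x features table keyed by sample_id."""
    frame = pd.read_csv(path, index_col="sample_id")
    if frame.index.has_duplicates or frame.columns.has_duplicates:
        raise ValueError(f"duplicate ids in {path}")
    return frame


def write_features_csv(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index_label="sample_id")


def read_fractions_csv(path: str | Path) -> pd.DataFrame:
    return read_features_csv(path)


def write_fractions_csv(A: pd.DataFrame, path: str | Path) -> None:
    A.to_csv(path, index_label="sample_id")


def read_reference_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_reference_csv(S: pd.DataFrame, path: str | Path) -> None:
    S.to_csv(path, index_label="subclone_id")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT gene sets: name, description, then tab-separated gene ids."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(GeneSet(name=parts[0], gene_ids=[g for g in parts[2:] if g]))
    return sets


def read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """NIfTI volume and its voxel spacing in mm."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def write_nifti(
    array: np.ndarray, path: str | Path, spacing: Sequence[float] = (1.0, 1.0, 1.0)
) -> None:
    import nibabel as nib

    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))
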