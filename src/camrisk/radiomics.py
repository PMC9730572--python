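"""Radiomic features from 3D image/mask pairs.

A deliberately small, exactly specified feature set: the surface-to-volume
shape ratio, gray-level dependence matrix (GLDM) features including
Dependence Entropy, and first-order intensity statistics.  Conventions:
images and masks share index space, spacing converts voxel indices to mm,
no resampling is performed, and gray levels are discretised with a fixed
bin width (CT default 25 HU).  Arbitrary precomputed feature tables are
the supported path for features outside this subset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.measure import marching_cubes, mesh_surface_area

EPS = 1e-16  # entropy guard


@dataclass
class RadiomicsConfig:
    """Extraction settings, recorded in the output table metadata."""

    bin_width: float = 25.0
    gldm_alpha: float = 0.0
    gldm_distance: int = 1
    surface_mode: str = "mesh"  # "mesh" (triangulated iso-surface) or "faces"
    surface_smooth_sigma: float = 1.0  # voxels, mesh mode only


def _check_pair(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    return mask


def discretize(image: np.ndarray, mask: np.ndarray, bin_width: float = 25.0) -> np.ndarray:
    """Fixed-bin-width gray levels over the mask: floor((v - min)/w) + 1.

    Returns an integer array of the image's shape with 0 outside the mask
    and levels >= 1 inside.  Invariant to intensity shifts.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask = _check_pair(image, mask)
    image = np.asarray(image, dtype=float)
    levels = np.zeros(image.shape, dtype=int)
    vmin = image[mask].min()
    levels[mask] = np.floor((image[mask] - vmin) / bin_width).astype(int) + 1
    return levels


def surface_volume_ratio(
    mask: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    mode: str = "mesh",
    smooth_sigma: float = 1.0,
) -> float:
    """Surface area / volume of the mask, in 1/mm.

    ``mesh`` triangulates the 0.5 iso-surface (marching cubes) after a
    light Gaussian anti-aliasing of the binary mask (``smooth_sigma`` in
    voxels; the staircase of a raw binary iso-surface otherwise inflates
    the area by ~9% independent of resolution).  ``faces`` counts exposed
    voxel faces (exact for axis-aligned solids).  Volume is always voxel
    count x voxel volume.
    """
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    volume = float(mask.sum()) * float(np.prod(spacing))
    if mode == "mesh":
        from scipy.ndimage import gaussian_filter

        pad = max(1, int(np.ceil(3 * smooth_sigma)))
        padded = np.pad(mask.astype(float), pad)
        if smooth_sigma > 0:
            smoothed = gaussian_filter(padded, smooth_sigma)
            if smoothed.max() <= 0.5:  # mask too thin to survive smoothing
                smoothed = padded
        else:
            smoothed = padded
        verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=tuple(spacing))
        area = float(mesh_surface_area(verts, faces))
    elif mode == "faces":
        area = 0.0
        for axis in range(3):
            face_area = float(np.prod(np.delete(spacing, axis)))
            padded = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
            exposed = np.abs(np.diff(padded.astype(int), axis=axis)).sum()
            area += face_area * float(exposed)
    else:
        raise ValueError(f"unknown surface mode {mode!r}")
    return area / volume


def gldm(
    image_levels: np.ndarray,
    mask: np.ndarray,
    alpha: float = 0.0,
    distance: int = 1,
) -> np.ndarray:
    """Gray-level dependence matrix P(i, j) (raw occurrence counts).

    For each masked voxel with level i, its dependence j is the number of
    in-mask neighbours within Chebyshev ``distance`` whose level differs
    from i by at most ``alpha``.  Row i-1 of the returned matrix counts
    voxels of level i by dependence j (column index).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    mask = _check_pair(image_levels, mask)
    levels = np.asarray(image_levels, dtype=int)
    d = distance
    padded_levels = np.pad(levels, d, constant_values=0)
    padded_mask = np.pad(mask, d, constant_values=False)
    shape = levels.shape
    dep = np.zeros(shape, dtype=int)
    center = padded_levels[d : d + shape[0], d : d + shape[1], d : d + shape[2]]
    for off in itertools.product(range(-d, d + 1), repeat=3):
        if off == (0, 0, 0):
            continue
        sl = tuple(slice(d + o, d + o + s) for o, s in zip(off, shape))
        neigh_levels = padded_levels[sl]
        neigh_mask = padded_mask[sl]
        dep += (neigh_mask & (np.abs(neigh_levels - center) <= alpha)).astype(int)
    n_levels = int(levels[mask].max())
    max_dep = int(dep[mask].max())
    P = np.zeros((n_levels, max_dep + 1))
    np.add.at(P, (levels[mask] - 1, dep[mask]), 1)
    return P


def gldm_dependence_entropy(P_normalized: np.ndarray) -> float:
    """Shannon entropy (bits) of the normalised dependence matrix."""
    P = np.asarray(P_normalized, dtype=float)
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("P must be normalised to sum 1")
    nz = P[P > 0]
    return float(-(nz * np.log2(nz + EPS)).sum())


def first_order(
    image: np.ndarray,
    mask: np.ndarray,
    bin_width: float = 25.0,
) -> dict[str, float]:
    """First-order intensity statistics over the masked voxels.

    Entropy is computed on the fixed-bin-width discretised levels.
    Skewness of a (near-)constant region is defined as 0.
    """
    mask = _check_pair(image, mask)
    v = np.asarray(image, dtype=float)[mask]
    mean = float(v.mean())
    var = float(v.var())
    if var > 0:
        skew = float(((v - mean) ** 3).mean() / var**1.5)
    else:
        skew = 0.0
    levels = discretize(image, mask, bin_width=bin_width)[mask]
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p + EPS)).sum())
    return {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Entropy": entropy,
        "Energy": float((v**2).sum()),
        "Minimum": float(v.min()),
        "Maximum": float(v.max()),
    }


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    config: RadiomicsConfig | None = None,
) -> dict[str, float]:
    """All implemented features for one image/mask pair."""
    config = config or RadiomicsConfig()
    out = {
        "original_shape_SurfaceVolumeRatio": surface_volume_ratio(
            mask, spacing, mode=config.surface_mode, smooth_sigma=config.surface_smooth_sigma
        )
    }
    levels = discretize(image, mask, bin_width=config.bin_width)
    P = gldm(levels, mask, alpha=config.gldm_alpha, distance=config.gldm_distance)
    out["original_gldm_DependenceEntropy"] = gldm_dependence_entropy(P / P.sum())
    for name, value in first_order(image, mask, bin_width=config.bin_width).items():
        out[f"original_firstorder_{name}"] = value
    return out


def extract_feature_table(
    image_mask_pairs: Mapping[str, tuple[np.ndarray, np.ndarray, Sequence[float]]]
    | Iterable[tuple[str, np.ndarray, np.ndarray, Sequence[float]]],
    config: RadiomicsConfig | None = None,
) -> pd.DataFrame:
    """Feature table over a collection of (sample, image, mask, spacing).

    Accepts either a mapping ``sample_id -> (image, mask, spacing)`` or an
    iterable of 4-tuples.  The extraction settings are recorded in
    ``result.attrs["config"]``; rows are deterministic functions of the
    inputs.
    """
    config = config or RadiomicsConfig()
    if isinstance(image_mask_pairs, Mapping):
        items = [(sid, *triple) for sid, triple in image_mask_pairs.items()]
    else:
        items = list(image_mask_pairs)
    rows = {}
    for sid, image, mask, spacing in items:
        rows[sid] = extract_features(image, mask, spacing, config=config)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    table.attrs["config"] = asdict(config)
    return table
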