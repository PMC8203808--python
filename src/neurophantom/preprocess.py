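"""Intensity normalization, head-size correction and voxel feature extraction.

Conventions (fixed and documented rather than tuned): image z-normalization
uses the population variance (divide by n); feature scaling uses the sample
variance (n-1). Zero-variance features get sd := 1 so the feature becomes a
constant 0 without disturbing the voxel index map. Every scaler records the
subject ids it was fit on, so leakage checks are possible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import BrainMask, VolumeImage


@dataclass
class FeatureMatrix:
    """Subjects x masked-voxel values with the map back to voxel space."""

    values: np.ndarray  # (n_subjects, n_features)
    index_map: np.ndarray  # (n_features, 3) voxel coordinates inside the mask
    subject_order: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        if self.values.shape[0] != len(self.subject_order):
            raise ValueError("row count must equal number of subject ids")
        if self.values.shape[1] != self.index_map.shape[0]:
            raise ValueError("feature count must match index map length")


@dataclass
class FeatureScaler:
    """Per-feature standardization fitted on a training set only."""

    mean: np.ndarray
    sd: np.ndarray
    fitted_on: list

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            raise ValueError("scaler sd must be strictly positive")


def znormalize_in_mask(img: VolumeImage, mask: BrainMask) -> VolumeImage:
    """Zero-mean unit-variance intensities within the brain mask.

    Population variance convention; voxels outside the mask are set to 0.
    Raises on a constant (zero-variance) image.
    """
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    vals = img.data[mask.data]
    sd = vals.std()  # population (ddof=0)
    if sd == 0:
        raise ValueError("degenerate image: zero variance within the brain mask")
    out = np.zeros_like(img.data)
    out[mask.data] = (vals - vals.mean()) / sd
    return img.copy_with(out)


def icv_normalize(img: VolumeImage, icv: float) -> VolumeImage:
    """Divide a modulated GM map by intracranial volume (head-size factor)."""
    if icv <= 0:
        raise ValueError(f"icv must be positive, got {icv}")
    return img.copy_with(img.data / icv)


def mask_index_map(mask: BrainMask) -> np.ndarray:
    """Stable (C-order) voxel coordinates of the mask foreground."""
    return np.argwhere(mask.data)


def vectorize(img: VolumeImage, mask: BrainMask) -> np.ndarray:
    """Within-mask voxel values as a feature row (C-order of the mask)."""
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    return img.data[mask.data].astype(np.float64)


def devectorize(row: np.ndarray, mask: BrainMask) -> VolumeImage:
    """Render a feature row back into a volume; outside-mask voxels are 0."""
    row = np.asarray(row, dtype=np.float64)
    if row.shape != (mask.n_voxels,):
        raise ValueError(
            f"row length {row.shape} does not match mask foreground {mask.n_voxels}"
        )
    out = np.zeros(mask.shape, dtype=np.float64)
    out[mask.data] = row
    return VolumeImage(out, spacing=mask.spacing, affine=mask.affine.copy())


def stack_features(
    imgs: dict[str, VolumeImage], mask: BrainMask, subject_order: list[str]
) -> FeatureMatrix:
    """Vectorize a set of images into a FeatureMatrix in the given order."""
    rows = np.stack([vectorize(imgs[s], mask) for s in subject_order])
    return FeatureMatrix(rows, mask_index_map(mask), list(subject_order))


def fit_feature_scaler(train: FeatureMatrix) -> FeatureScaler:
    """Per-feature mean/sd from the training rows (sample variance, ddof=1)."""
    if train.values.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit a scaler")
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)  # zero-variance features become constant 0
    return FeatureScaler(mean=mean, sd=sd, fitted_on=list(train.subject_order))


def apply_scaler(scaler: FeatureScaler, X: FeatureMatrix) -> FeatureMatrix:
    """Apply a fitted scaler (no refit) to any feature matrix."""
    if X.values.shape[1] != scaler.mean.shape[0]:
        raise ValueError("feature count differs from the fitted scaler")
    vals = (X.values - scaler.mean) / scaler.sd
    return FeatureMatrix(vals, X.index_map, list(X.subject_order))
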