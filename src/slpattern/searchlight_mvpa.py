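"""Searchlight classification: sphere feature extraction, leakage-free
standardization, SVM-RBF leave-one-out cross-validation, accuracy maps.

For every mask voxel a sphere of configurable physical radius supplies the
feature vector (one value per in-mask sphere voxel, per subject).  Each
LOOCV fold standardizes features on its training rows only, applies those
parameters to the held-out row, fits an RBF-kernel SVM with default
parameters (C=1, gamma=1/V) and predicts the held-out subject.  The
fraction of correct held-out predictions is assigned to the sphere centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _svm
from .volume_geometry import OffsetSet, VolumeGrid, in_mask_sphere, sphere_offsets

__all__ = [
    "FeatureMatrix",
    "SvmConfig",
    "AccuracyMap",
    "extract_features",
    "loocv_accuracy",
    "residualize_covariates",
    "searchlight_map",
]


@dataclass
class FeatureMatrix:
    """Subjects x voxels matrix for one searchlight sphere."""

    values: np.ndarray
    subject_ids: list
    voxel_indices: np.ndarray  # (V, 3) int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2D (subjects x voxels)")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")


@dataclass
class SvmConfig:
    """RBF-kernel SVM settings; kernel and normalization are fixed.

    gamma may be a positive float or the string "1/V" (one over the
    feature count of the sphere actually classified — the historical
    libsvm default).
    """

    C: float = 1.0
    gamma: object = "1/V"
    backend: str = "auto"

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.gamma != "1/V":
            self.gamma = float(self.gamma)
            if self.gamma <= 0:
                raise ValueError(f"gamma must be positive, got {self.gamma}")

    def resolve_gamma(self, n_features: int) -> float:
        if self.gamma == "1/V":
            return 1.0 / max(n_features, 1)
        return self.gamma


@dataclass
class AccuracyMap:
    """Per-voxel LOOCV accuracy; NaN outside the mask."""

    grid: VolumeGrid
    accuracy: np.ndarray
    n_subjects: int

    def __post_init__(self):
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if self.accuracy.shape != self.grid.shape:
            raise ValueError("accuracy map shape does not match grid")


def extract_features(volumes, center, offsets: OffsetSet, grid: VolumeGrid,
                     subject_ids=None) -> FeatureMatrix:
    """Extract the sphere feature matrix centred at ``center``.

    volumes: (n_subjects, *grid.shape) array.  Column order follows the
    lexicographic order of the sphere's member voxel indices, identical
    across subjects.
    """
    volumes = np.asarray(volumes)
    members = in_mask_sphere(center, offsets, grid)
    vals = volumes[:, members[:, 0], members[:, 1], members[:, 2]]
    ids = list(subject_ids) if subject_ids is not None else list(range(len(volumes)))
    return FeatureMatrix(values=vals, subject_ids=ids, voxel_indices=members)


def _check_labels(labels, n: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise ValueError(f"labels shape {labels.shape} does not match {n} subjects")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"labels must be binary with both classes present, got {classes}")
    y = (labels == classes[1]).astype(np.int64)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("each class needs at least 2 members for LOOCV")
    return y


def _loocv_accuracy_array(X: np.ndarray, y: np.ndarray, config: SvmConfig) -> float:
    n, n_feat = X.shape
    gamma = config.resolve_gamma(n_feat)
    # centre once so the leave-one-out moment identities below are
    # numerically safe regardless of the raw value scale
    X = X - X.mean(axis=0)
    S = X.sum(axis=0)
    X2 = X * X
    Q = X2.sum(axis=0)
    col_scale = np.sqrt(Q / n)
    correct = 0
    rows = np.arange(n)
    for i in range(n):
        mu = (S - X[i]) / (n - 1)
        var = (Q - X2[i]) / (n - 1) - mu * mu
        sd = np.sqrt(np.clip(var, 0.0, None))
        # zero-variance training columns map to 0 (keeps dimension stable)
        ok = sd > 1e-9 * np.maximum(col_scale, 1e-300)
        inv = np.where(ok, 1.0 / np.where(ok, sd, 1.0), 0.0)
        Z = (X - mu) * inv
        pred = _svm.fit_predict(Z[rows != i], y[rows != i], Z[i : i + 1],
                                config.C, gamma, backend=config.backend)
        correct += int(pred[0] == y[i])
    return correct / n


def loocv_accuracy(features, labels, config: SvmConfig = None) -> float:
    """Leave-one-out cross-validated SVM-RBF accuracy.

    Per fold: per-feature standardization fit on the N-1 training rows
    (zero-variance training columns mapped to 0), training parameters
    applied to the held-out row, RBF SVM fit, held-out row predicted.

    Returns correct predictions / N — always a multiple of 1/N.
    """
    config = config or SvmConfig()
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    y = _check_labels(labels, len(X))
    return _loocv_accuracy_array(X, y, config)


def residualize_covariates(volumes, covariates) -> np.ndarray:
    """Replace each voxel's values by residuals from an OLS fit on covariates.

    covariates: (n_subjects, k) numeric array; an intercept is added.
    Applied across subjects voxel-wise (the optional pre-classification
    covariate-removal variant; off by default in the pipeline).
    """
    volumes = np.asarray(volumes, dtype=float)
    n = len(volumes)
    Z = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    flat = volumes.reshape(n, -1)
    beta, *_ = np.linalg.lstsq(Z, flat, rcond=None)
    return (flat - Z @ beta).reshape(volumes.shape)


def searchlight_map(volumes, labels, grid: VolumeGrid, radius_mm: float,
                    config: SvmConfig = None, covariates=None,
                    discard_partial: bool = False) -> AccuracyMap:
    """LOOCV accuracy at every mask voxel for a sphere of ``radius_mm``.

    Spheres truncated by the mask or grid edge keep their in-mask voxels
    (set ``discard_partial=True`` to leave truncated centres NaN).
    Deterministic given inputs; voxels are independent.
    """
    config = config or SvmConfig()
    volumes = np.asarray(volumes, dtype=float)
    if radius_mm < 0:
        raise ValueError(f"radius_mm must be nonnegative, got {radius_mm}")
    y = _check_labels(labels, len(volumes))
    if covariates is not None:
        volumes = residualize_covariates(volumes, covariates)

    offsets = sphere_offsets(radius_mm, grid.voxel_size)
    full = len(offsets)
    flat = np.ascontiguousarray(volumes.reshape(len(volumes), -1))
    strides = np.array([grid.shape[1] * grid.shape[2], grid.shape[2], 1])
    mask_flat = grid.mask.ravel()
    shape = np.asarray(grid.shape)

    acc = np.full(grid.shape, np.nan)
    centers = grid.mask_indices()
    offs = offsets.offsets
    for c in centers:
        pts = c[None, :] + offs
        inb = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[inb]
        lin = pts @ strides
        lin = lin[mask_flat[lin]]
        if discard_partial and len(lin) < full:
            continue
        X = flat[:, lin]
        acc[tuple(c)] = _loocv_accuracy_array(X, y, config)
    return AccuracyMap(grid=grid, accuracy=acc, n_subjects=len(volumes))
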