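"""Post-hoc group statistics inside detected clusters.

Covariate-adjusted voxel-wise t-maps (OLS with group + nuisance
covariates), Monte-Carlo cluster-extent thresholds estimated from smoothed
null noise fields, sign-separated extent-corrected clusters, and Spearman
correlation of per-subject cluster mean volume with VAS change.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .cluster_inference import Cluster, ClusterSet, connectivity_structure
from .synthetic_cohort import smooth_volume
from .volume_geometry import VolumeGrid

__all__ = [
    "GlmDesign",
    "ExtentThreshold",
    "DegenerateDesignError",
    "glm_tmap",
    "mc_extent_threshold",
    "apply_correction",
    "spearman_cluster_dvas",
]


class DegenerateDesignError(ValueError):
    """Raised when the design matrix is rank deficient."""


@dataclass
class GlmDesign:
    """Design for the voxel-wise group contrast: intercept + group + covariates."""

    group: np.ndarray  # binary indicator per subject
    covariates: np.ndarray = None  # (n, k) or None
    covariate_names: list = None

    def __post_init__(self):
        self.group = np.asarray(self.group, dtype=float)
        u = np.unique(self.group)
        if not np.all(np.isin(u, (0.0, 1.0))) or len(u) != 2:
            raise ValueError("group must be a binary 0/1 indicator with both groups present")
        if self.group.sum() < 2 or (1 - self.group).sum() < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != len(self.group):
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != len(self.group):
                raise ValueError("covariates do not match subject count")
        if self.covariate_names is None and self.covariates is not None:
            self.covariate_names = [f"cov{i}" for i in range(self.covariates.shape[1])]

    def matrix(self):
        """(X, dropped) — full-rank design matrix; zero-variance covariates dropped."""
        n = len(self.group)
        cols = [np.ones(n), self.group]
        dropped = []
        if self.covariates is not None:
            for j in range(self.covariates.shape[1]):
                c = self.covariates[:, j]
                if np.ptp(c) == 0:
                    name = self.covariate_names[j]
                    dropped.append(name)
                    warnings.warn(f"covariate {name!r} has zero variance; dropped")
                else:
                    cols.append(c)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateDesignError(
                "design matrix is rank deficient (a covariate is collinear with "
                "the group indicator or intercept)"
            )
        return X, dropped


@dataclass
class ExtentThreshold:
    """Monte-Carlo cluster-extent correction settings and result."""

    voxel_p: float = 0.01
    alpha: float = 0.05
    n_iterations: int = 1000
    fwhm_mm: float = 8.0
    connectivity: int = 18
    seed: int = 0
    min_cluster_size: int = None  # estimated by mc_extent_threshold

    def __post_init__(self):
        if not 0 < self.voxel_p < 1:
            raise ValueError(f"voxel_p must be in (0,1), got {self.voxel_p}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0,1], got {self.alpha}")
        if self.n_iterations < 100:
            warnings.warn(
                f"n_iterations={self.n_iterations} < 100: extent threshold "
                "estimate will be unstable"
            )


def glm_tmap(volumes, design: GlmDesign, mask=None, restrict_to: ClusterSet = None):
    """Voxel-wise OLS t-map for the group coefficient.

    Fits GM value ~ intercept + group + covariates at every analysis voxel
    (optionally restricted to a ClusterSet's labelled voxels) and returns
    ``(tmap, df)`` with NaN outside the analysis set.  df = N - rank(X).
    """
    volumes = np.asarray(volumes, dtype=float)
    n = len(volumes)
    X, _ = design.matrix()
    if len(X) != n:
        raise ValueError("design does not match number of subjects")
    df = n - X.shape[1]
    if df < 1:
        raise DegenerateDesignError("no residual degrees of freedom")

    if restrict_to is not None:
        analysis = restrict_to.labels > 0
    elif mask is not None:
        analysis = np.asarray(mask, dtype=bool)
    else:
        analysis = np.ones(volumes.shape[1:], dtype=bool)

    Y = volumes.reshape(n, -1)[:, analysis.ravel()]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / se
    tmap = np.full(volumes.shape[1:], np.nan)
    tmap[analysis] = t
    return tmap, df


def mc_extent_threshold(grid: VolumeGrid, cfg: ExtentThreshold) -> int:
    """Estimate the cluster-size threshold controlling FWE at cfg.alpha.

    Each iteration simulates an independent Gaussian field on the grid,
    smooths it to cfg.fwhm_mm, standardizes within the mask, thresholds
    |z| at the two-tailed voxel_p quantile and records the largest
    connected-component size.  Returns the smallest integer s such that
    the fraction of iterations whose maximum size is >= s does not
    exceed alpha.
    """
    rng = np.random.default_rng(cfg.seed)
    zthr = stats.norm.ppf(1 - cfg.voxel_p / 2)
    structure = connectivity_structure(cfg.connectivity)
    mask = grid.mask
    max_sizes = np.zeros(cfg.n_iterations, dtype=int)
    for it in range(cfg.n_iterations):
        noise = rng.standard_normal(grid.shape)
        sm = smooth_volume(noise, grid, cfg.fwhm_mm)
        vals = sm[mask]
        z = np.zeros(grid.shape)
        z[mask] = (vals - vals.mean()) / vals.std(ddof=0)
        supra = np.abs(z) > zthr
        supra &= mask
        if supra.any():
            lab, nlab = ndimage.label(supra, structure=structure)
            if nlab:
                max_sizes[it] = np.bincount(lab.ravel())[1:].max()
    # smallest s with P(max >= s) <= alpha
    s = 1
    while (max_sizes >= s).mean() > cfg.alpha:
        s += 1
    return int(s)


def apply_correction(tmap, df, grid: VolumeGrid, threshold: ExtentThreshold):
    """Extent-corrected, sign-separated clusters of a t-map.

    Voxels with two-tailed p < voxel_p are split by the sign of t,
    labelled under the configured connectivity, and components of size
    >= threshold.min_cluster_size survive.  Returns a dict with keys
    "negative" (group1 < group2) and "positive", each a ClusterSet whose
    cluster peak is the maximal |t| voxel.
    """
    if threshold.min_cluster_size is None:
        raise ValueError("threshold.min_cluster_size has not been estimated")
    tmap = np.asarray(tmap, dtype=float)
    defined = np.isfinite(tmap)
    tcrit = stats.t.ppf(1 - threshold.voxel_p / 2, df)
    structure = connectivity_structure(threshold.connectivity)

    out = {}
    for direction, sel in (("positive", tmap > tcrit), ("negative", tmap < -tcrit)):
        supra = sel & defined
        lab, nlab = ndimage.label(supra, structure=structure)
        comps = []
        for l in range(1, nlab + 1):
            members = np.argwhere(lab == l)
            if len(members) >= threshold.min_cluster_size:
                comps.append(members)
        comps.sort(key=len, reverse=True)
        keep = np.zeros(tmap.shape, dtype=np.int32)
        clusters = []
        for new_lab, members in enumerate(comps, start=1):
            keep[members[:, 0], members[:, 1], members[:, 2]] = new_lab
            tv = tmap[members[:, 0], members[:, 1], members[:, 2]]
            order = np.lexsort((members[:, 2], members[:, 1], members[:, 0]))
            members = members[order]
            tv = tv[order]
            ipk = int(np.argmax(np.abs(tv)))
            clusters.append(
                Cluster(
                    label=new_lab,
                    size=len(members),
                    peak=tuple(int(v) for v in members[ipk]),
                    peak_p=float(2 * stats.t.sf(abs(tv[ipk]), df)),
                    peak_accuracy=float(tv[ipk]),  # stores peak t for t-map clusters
                    members=members,
                )
            )
        out[direction] = ClusterSet(labels=keep, clusters=clusters)
    return out


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-tailed exact p by full enumeration of rank permutations (n <= 9)."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    rhos = (rx_c[perms] @ ry_c) / denom
    return float((np.abs(rhos) >= abs(rho_obs) - 1e-12).mean())


def spearman_cluster_dvas(cluster_mean_gm, dvas):
    """Spearman rank correlation of cluster mean GM volume with VAS change.

    Average ranks for ties; two-tailed p — exact permutation enumeration
    for n <= 9, t-approximation otherwise.  Returns ``(rho, p)``.
    """
    x = np.asarray(cluster_mean_gm, dtype=float)
    y = np.asarray(dvas, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1D vectors")
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, p
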