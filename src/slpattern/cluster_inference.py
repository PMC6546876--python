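"""Binomial-null inference on accuracy maps and permutation validation.

Under the null of indistinguishable groups the number of correctly
classified subjects follows Bi(n, 1/2); per voxel the upper-tail
probability P(X >= k) converts accuracy into a p-value.  Suprathreshold
voxels are grouped into maximal 18-connected components (6 faces + 12
edges by default), size-filtered, and each surviving cluster is validated
by re-running LOOCV under random relabelings of the groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage

from .searchlight_mvpa import AccuracyMap, SvmConfig, loocv_accuracy
from .volume_geometry import VolumeGrid

__all__ = [
    "PMap",
    "Cluster",
    "ClusterSet",
    "InferenceConfig",
    "binomial_tail_p",
    "accuracy_to_pmap",
    "connectivity_structure",
    "label_clusters",
    "permutation_test_cluster",
    "run_cluster_permutations",
]


@dataclass
class PMap:
    """Per-voxel binomial tail p-values; NaN outside the mask."""

    grid: VolumeGrid
    p: np.ndarray
    n_subjects: int

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != self.grid.shape:
            raise ValueError("p-map shape does not match grid")


@dataclass
class Cluster:
    label: int
    size: int
    peak: tuple  # voxel index of minimal p
    peak_p: float
    peak_accuracy: float
    members: np.ndarray  # (size, 3) int
    perm_p: float = None


@dataclass
class ClusterSet:
    labels: np.ndarray  # int label volume, 0 = background
    clusters: list

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass
class InferenceConfig:
    voxel_alpha: float = 1e-4
    min_size: int = 50
    connectivity: int = 18
    n_permutations: int = 1000
    perm_alpha: float = 0.05
    seed: int = 0
    strict_tail: bool = False  # P(X > k) instead of P(X >= k)

    def __post_init__(self):
        if not 0 < self.voxel_alpha < 1:
            raise ValueError(f"voxel_alpha must be in (0,1), got {self.voxel_alpha}")
        if self.min_size < 1:
            raise ValueError(f"min_size must be >= 1, got {self.min_size}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")


def binomial_tail_p(k: int, n: int, strict: bool = False) -> float:
    """Exact upper-tail probability of Bi(n, 1/2).

    Returns P(X >= k) (or P(X > k) with ``strict=True``), computed by
    integer summation of binomial coefficients over 2**n.
    """
    k, n = int(k), int(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must satisfy 0 <= k <= n, got k={k}, n={n}")
    lo = k + 1 if strict else k
    total = sum(math.comb(n, j) for j in range(lo, n + 1))
    return float(Fraction(total, 2**n))


def accuracy_to_pmap(acc: AccuracyMap, strict: bool = False) -> PMap:
    """Convert an accuracy map to a binomial-tail p-value map.

    k = round(accuracy * n) is exact because LOOCV accuracies are
    multiples of 1/n.
    """
    n = acc.n_subjects
    a = acc.accuracy
    defined = np.isfinite(a)
    if np.any((a[defined] < 0) | (a[defined] > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    # table lookup: p is a function of k alone
    table = np.array([binomial_tail_p(k, n, strict=strict) for k in range(n + 1)])
    p = np.full(acc.accuracy.shape, np.nan)
    k = np.rint(a[defined] * n).astype(int)
    p[defined] = table[k]
    return PMap(grid=acc.grid, p=p, n_subjects=n)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 binary structuring element for 6/18/26-connectivity."""
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def label_clusters(pmap: PMap, cfg: InferenceConfig, accuracy: AccuracyMap = None) -> ClusterSet:
    """Extract suprathreshold connected components of size >= min_size.

    Voxels with p < voxel_alpha are partitioned into maximal components
    under the configured connectivity; surviving components are returned
    ordered by size descending.  Peak voxel = minimal p (ties broken by
    lexicographic voxel index).  An empty ClusterSet is a valid result.
    """
    supra = np.zeros(pmap.p.shape, dtype=bool)
    defined = np.isfinite(pmap.p)
    supra[defined] = pmap.p[defined] < cfg.voxel_alpha
    raw_labels, n_raw = ndimage.label(supra, structure=connectivity_structure(cfg.connectivity))

    clusters = []
    keep = np.zeros(raw_labels.shape, dtype=np.int32)
    comps = []
    for lab in range(1, n_raw + 1):
        members = np.argwhere(raw_labels == lab)
        if len(members) >= cfg.min_size:
            comps.append(members)
    comps.sort(key=len, reverse=True)
    for new_lab, members in enumerate(comps, start=1):
        keep[members[:, 0], members[:, 1], members[:, 2]] = new_lab
        pvals = pmap.p[members[:, 0], members[:, 1], members[:, 2]]
        best = np.lexsort((members[:, 2], members[:, 1], members[:, 0]))
        members_sorted = members[best]
        pvals_sorted = pvals[best]
        imin = int(np.argmin(pvals_sorted))  # first minimal p in lexicographic order
        peak = tuple(int(v) for v in members_sorted[imin])
        peak_acc = float(accuracy.accuracy[peak]) if accuracy is not None else float("nan")
        clusters.append(
            Cluster(
                label=new_lab,
                size=len(members),
                peak=peak,
                peak_p=float(pvals_sorted[imin]),
                peak_accuracy=peak_acc,
                members=members_sorted,
            )
        )
    return ClusterSet(labels=keep, clusters=clusters)


def permutation_test_cluster(features, labels, config: SvmConfig = None,
                             n_perm: int = 1000, seed: int = 0,
                             return_null: bool = False):
    """Label-permutation p-value for one cluster's LOOCV accuracy.

    The observed accuracy is recomputed on the true labels; each of
    ``n_perm`` seeded shuffles of the label vector (class counts
    preserved by construction) yields a null accuracy.  The add-one
    estimate p = (1 + #{null >= observed}) / (n_perm + 1) never returns 0;
    its smallest achievable value is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    config = config or SvmConfig()
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = loocv_accuracy(features, labels, config)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = loocv_accuracy(features, rng.permutation(labels), config)
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    if return_null:
        return p, observed, null
    return p, observed


def run_cluster_permutations(volumes, labels, clusters: ClusterSet,
                             svm_config: SvmConfig = None,
                             cfg: InferenceConfig = None) -> ClusterSet:
    """Permutation-test every cluster on its full voxel set (in place).

    Per-cluster seeds are derived deterministically from cfg.seed so
    results do not depend on cluster evaluation order.
    """
    cfg = cfg or InferenceConfig()
    svm_config = svm_config or SvmConfig()
    volumes = np.asarray(volumes, dtype=float)
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.spawn(max(len(clusters.clusters), 1))
    for cluster, sub_ss in zip(clusters.clusters, seeds):
        m = cluster.members
        feats = volumes[:, m[:, 0], m[:, 1], m[:, 2]]
        seed = int(sub_ss.generate_state(1)[0])
        cluster.perm_p, _ = permutation_test_cluster(
            feats, labels, svm_config, n_perm=cfg.n_permutations, seed=seed
        )
    return clusters
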