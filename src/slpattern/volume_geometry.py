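"""Volume grid geometry, masks, NIfTI I/O, and searchlight sphere offsets.

Every map handled by the package lives on a :class:`VolumeGrid` — a voxel
lattice with physical spacing in millimetres, a world-coordinate affine,
and a boolean analysis mask.  Searchlight spheres are represented as sets
of integer voxel offsets from a centre voxel (:class:`OffsetSet`), computed
from a physical radius in mm.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "OffsetSet",
    "sphere_offsets",
    "in_mask_sphere",
    "read_volume",
    "read_mask",
    "write_volume",
]


def _as_triple(x, dtype=float) -> tuple:
    t = tuple(dtype(v) for v in np.atleast_1d(np.asarray(x)).ravel())
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValueError(f"expected a scalar or 3-vector, got {x!r}")
    return t


@dataclass
class VolumeGrid:
    """A 3D voxel lattice with physical spacing, affine and analysis mask.

    Parameters
    ----------
    shape : tuple of 3 int
        Grid dimensions in voxels.
    voxel_size : tuple of 3 float
        Voxel spacing along each axis, in mm; strictly positive.
    affine : (4, 4) ndarray, optional
        Voxel-to-world transform in mm.  Defaults to a diagonal scaling
        by ``voxel_size`` centred at the origin of voxel (0, 0, 0).
    mask : ndarray of bool, optional
        Analysis mask; defaults to all-true.  Must match ``shape`` and
        contain at least one true voxel.
    """

    shape: tuple
    voxel_size: tuple
    affine: np.ndarray = None
    mask: np.ndarray = None

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        self.voxel_size = _as_triple(self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be strictly positive, got {self.voxel_size}")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match grid shape {self.shape}"
            )
        if not self.mask.any():
            raise ValueError("mask must contain at least one true voxel")

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    def mask_indices(self) -> np.ndarray:
        """(n, 3) integer indices of mask-true voxels, C order."""
        return np.argwhere(self.mask)

    def voxel_to_world(self, idx) -> np.ndarray:
        """Map voxel indices (n, 3) to world mm coordinates via the affine."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        hom = np.c_[idx, np.ones(len(idx))]
        return (hom @ self.affine.T)[:, :3]

    def with_mask(self, mask: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(self.shape, self.voxel_size, self.affine.copy(), mask)


@dataclass
class OffsetSet:
    """Integer voxel offsets forming a searchlight sphere."""

    radius_mm: float
    voxel_size: tuple
    offsets: np.ndarray  # (n, 3) int

    def __len__(self) -> int:
        return len(self.offsets)


def sphere_offsets(radius_mm: float, voxel_size) -> OffsetSet:
    """Integer voxel offsets within ``radius_mm`` of a centre voxel.

    Membership uses centre-to-centre Euclidean distance in mm with an
    inclusive boundary (``<= radius_mm``).  The origin offset is always
    included.

    Parameters
    ----------
    radius_mm : float
        Sphere radius in mm, nonnegative.
    voxel_size : scalar or 3-vector
        Voxel spacing in mm, strictly positive.

    Returns
    -------
    OffsetSet
        Offsets sorted lexicographically, origin included.
    """
    if radius_mm < 0:
        raise ValueError(f"radius_mm must be nonnegative, got {radius_mm}")
    vs = _as_triple(voxel_size)
    if any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size must be strictly positive, got {voxel_size}")
    half = [int(np.floor(radius_mm / v)) for v in vs]
    ax = [np.arange(-h, h + 1) for h in half]
    dx, dy, dz = np.meshgrid(*ax, indexing="ij")
    offs = np.column_stack([dx.ravel(), dy.ravel(), dz.ravel()])
    dist2 = (offs.astype(float) * np.asarray(vs)) ** 2
    keep = dist2.sum(axis=1) <= radius_mm**2 + 1e-12
    offs = offs[keep]
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0]))
    return OffsetSet(float(radius_mm), vs, offs[order].astype(np.int64))


def in_mask_sphere(center, offsets: OffsetSet, grid: VolumeGrid) -> np.ndarray:
    """Sphere member voxels clipped to grid bounds and mask.

    Parameters
    ----------
    center : 3-vector of int
        Centre voxel index; must lie inside the mask.
    offsets : OffsetSet
    grid : VolumeGrid

    Returns
    -------
    (k, 3) ndarray of int
        Indices of sphere voxels inside both the grid and the mask.
        Always contains the centre.
    """
    center = np.asarray(center, dtype=np.int64)
    if center.shape != (3,):
        raise ValueError(f"center must be a 3-vector, got {center!r}")
    if np.any(center < 0) or np.any(center >= np.asarray(grid.shape)):
        raise ValueError(f"center {tuple(center)} outside grid bounds {grid.shape}")
    if not grid.mask[tuple(center)]:
        raise ValueError(f"center {tuple(center)} is outside the mask")
    pts = center[None, :] + offsets.offsets
    inb = np.all((pts >= 0) & (pts < np.asarray(grid.shape)), axis=1)
    pts = pts[inb]
    inm = grid.mask[pts[:, 0], pts[:, 1], pts[:, 2]]
    return pts[inm]


def _grid_from_img(img, mask=None) -> VolumeGrid:
    shape = img.shape[:3]
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(shape, zooms, np.asarray(img.affine), mask)


def read_volume(path):
    """Read a NIfTI image.

    Returns ``(data, grid)`` where data is a 3D array, or a 4D array with
    the subject/volume axis FIRST for 4D images.  The grid mask defaults
    to all-true; attach an analysis mask with :func:`read_mask` /
    :meth:`VolumeGrid.with_mask`.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as e:  # corrupt / unreadable
        raise IOError(f"failed to read NIfTI file {path}: {e}") from e
    grid = _grid_from_img(img)
    if data.ndim == 4:
        data = np.moveaxis(data, -1, 0)
    elif data.ndim != 3:
        raise IOError(f"{path}: expected a 3D or 4D image, got shape {data.shape}")
    return data, grid


def read_mask(path) -> VolumeGrid:
    """Read a binary mask NIfTI as a VolumeGrid (nonzero voxels are true)."""
    data, grid = read_volume(path)
    if data.ndim != 3:
        raise IOError(f"{path}: mask must be a 3D image")
    return grid.with_mask(data != 0)


def write_volume(data, grid: VolumeGrid, path) -> None:
    """Write a 3D map (or a 4D stack, subject axis first) as NIfTI-1."""
    data = np.asarray(data)
    if data.ndim == 4:
        if data.shape[1:] != grid.shape:
            raise IOError(
                f"data shape {data.shape[1:]} does not match grid shape {grid.shape}"
            )
        out = np.moveaxis(data, 0, -1)
    elif data.ndim == 3:
        if data.shape != grid.shape:
            raise IOError(
                f"data shape {data.shape} does not match grid shape {grid.shape}"
            )
        out = data
    else:
        raise IOError(f"expected 3D or 4D data, got shape {data.shape}")
    img = nib.Nifti1Image(np.asarray(out, dtype=np.float64), grid.affine)
    img.header.set_zooms(grid.voxel_size + ((1.0,) if out.ndim == 4 else ()))
    nib.save(img, str(path))
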