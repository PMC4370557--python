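"""Voxel-grid geometry, masks, searchlight spheres, smoothing and volume I/O.

All analyses in this package operate on subject-level contrast volumes that
share a common isotropic voxel lattice (default 3 mm, the resolution the
contrast maps are resampled to).  This module defines the grid/mask/stack
containers, the lattice-sphere geometry used by the searchlight, Gaussian
smoothing with the conventional FWHM parameterisation, and NIfTI/CSV I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "MaskVolume",
    "SubjectVolumeStack",
    "SearchlightSpec",
    "StatMap",
    "fwhm_to_sigma",
    "sphere_offsets",
    "searchlight_neighbors",
    "neighbor_table",
    "gaussian_smooth",
    "read_nifti",
    "write_nifti",
    "read_cohort_table",
    "GROUP_LABELS",
]

#: group column coding: patients are the positive class throughout.
GROUP_LABELS = {"patient": 1, "control": -1}


@dataclass(frozen=True)
class VoxelGrid:
    """An isotropic 3-D voxel lattice with a voxel-to-world affine.

    Parameters
    ----------
    dims:
        Grid extent in voxels along x, y, z.
    voxel_size_mm:
        Isotropic voxel edge length in mm (default 3, the common resampled
        resolution for group-level fMRI analyses).
    affine:
        4x4 voxel-index -> world-coordinate (mm) map.  Defaults to a scaled
        identity.  Anisotropic affines are rejected: distances inside the
        searchlight are computed in voxel units and would be silently wrong
        on an anisotropic lattice.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: float = 3.0
    affine: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        object.__setattr__(self, "dims", dims)
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        aff = self.affine
        if aff is None:
            aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff = np.asarray(aff, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine must be invertible")
        scales = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
        if not np.allclose(scales, self.voxel_size_mm, rtol=1e-6):
            raise ValueError(
                "anisotropic or inconsistent affine: voxel scales "
                f"{scales} do not match voxel_size_mm={self.voxel_size_mm}"
            )
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def voxel_to_world(self, index: Sequence[float]) -> np.ndarray:
        """Map a voxel index triple to world (mm) coordinates."""
        idx = np.asarray(index, dtype=float)
        return (self.affine @ np.append(idx, 1.0))[:3]

    def compatible(self, other: "VoxelGrid") -> bool:
        return self.dims == other.dims and np.allclose(self.affine, other.affine)


@dataclass
class MaskVolume:
    """A binary mask (ROI or analysis volume) on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    data: np.ndarray
    name: str = "mask"

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {data.shape} does not match grid dims {self.grid.dims}"
            )
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask must be binary")
            data = data.astype(bool)
        if not data.any():
            raise ValueError("mask is empty (no voxels set)")
        self.data = data

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """(n, 3) integer indices of set voxels in C order."""
        return np.argwhere(self.data)


@dataclass
class StatMap:
    """A per-voxel scalar map (accuracy, t, rho, p, ...) on a grid.

    Voxels outside the analysis mask hold NaN.
    """

    grid: VoxelGrid
    data: np.ndarray
    name: str = "stat"

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.shape != self.grid.dims:
            raise ValueError("stat map shape does not match grid dims")
        self.data = data

    def values_in(self, mask: MaskVolume) -> np.ndarray:
        return self.data[mask.data]

    def peak(self, mask: MaskVolume | None = None):
        """(index triple, value) of the maximum, optionally within a mask."""
        data = self.data.copy()
        if mask is not None:
            data[~mask.data] = -np.inf
        data[~np.isfinite(data)] = -np.inf
        flat = int(np.argmax(data))
        idx = np.unravel_index(flat, data.shape)
        return tuple(int(i) for i in idx), float(data[idx])


@dataclass
class SubjectVolumeStack:
    """Per-subject scalar volumes (contrast maps) on a shared grid."""

    grid: VoxelGrid
    subject_ids: list[str]
    data: np.ndarray  # (n_subjects, *dims)
    mask: MaskVolume | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 4 or data.shape[1:] != self.grid.dims:
            raise ValueError(
                f"stack shape {data.shape} incompatible with grid {self.grid.dims}"
            )
        if len(self.subject_ids) != data.shape[0]:
            raise ValueError("subject_ids length does not match stack")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject_ids must be unique")
        if self.mask is not None:
            if not self.mask.grid.compatible(self.grid):
                raise ValueError("mask grid differs from stack grid")
            if not np.isfinite(data[:, self.mask.data]).all():
                raise ValueError("non-finite values inside analysis mask")
        self.data = data

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def flat(self) -> np.ndarray:
        """(n_subjects, n_voxels) view in C order, for the searchlight kernels."""
        return self.data.reshape(self.n_subjects, -1)

    def subset(self, keep: np.ndarray) -> "SubjectVolumeStack":
        keep = np.asarray(keep)
        ids = [sid for sid, k in zip(self.subject_ids, keep) if k]
        return SubjectVolumeStack(self.grid, ids, self.data[keep], self.mask)


@dataclass(frozen=True)
class SearchlightSpec:
    """Spherical searchlight definition.

    ``diameter_voxels`` is the sphere diameter in voxel units (6 for the
    classification searchlight, 4 for the ROI-restricted regression
    searchlight).  Membership is inclusive: every integer offset with
    Euclidean norm <= diameter/2 belongs to the sphere.
    """

    diameter_voxels: float = 6
    restrict_to_mask: bool = False

    def __post_init__(self):
        if self.diameter_voxels < 1:
            raise ValueError("searchlight diameter must be >= 1 voxel")


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full-width-half-maximum to its standard deviation."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def sphere_offsets(diameter_voxels: float) -> np.ndarray:
    """Integer offset triples within a sphere of the given diameter.

    Returns all (dx, dy, dz) with dx²+dy²+dz² <= (diameter/2)², in
    lexicographic order.  Diameter 6 yields 123 offsets, diameter 4 yields
    33, diameter 2 yields 7 (center plus face neighbours).
    """
    if diameter_voxels < 1:
        raise ValueError("diameter must be >= 1")
    r = diameter_voxels / 2.0
    rr = int(np.floor(r))
    ax = np.arange(-rr, rr + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r * r + 1e-9
    offs = np.stack([dx[keep], dy[keep], dz[keep]], axis=1)
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0]))
    return offs[order]


def searchlight_neighbors(
    center: Sequence[int],
    spec: SearchlightSpec,
    mask: MaskVolume,
) -> np.ndarray:
    """Voxel indices of the searchlight sphere centred at ``center``.

    The sphere is clipped at the grid boundary.  With ``restrict_to_mask``
    it is additionally intersected with the mask.  The center (which must be
    inside the mask) is always a member.
    """
    center = np.asarray(center, dtype=int)
    if center.shape != (3,):
        raise ValueError("center must be a voxel index triple")
    dims = mask.grid.dims
    if not ((0 <= center).all() and (center < dims).all() and mask.data[tuple(center)]):
        raise ValueError(f"center {tuple(center)} is outside the mask")
    pts = center[None, :] + sphere_offsets(spec.diameter_voxels)
    inb = ((pts >= 0) & (pts < np.asarray(dims))).all(axis=1)
    pts = pts[inb]
    if spec.restrict_to_mask:
        pts = pts[mask.data[pts[:, 0], pts[:, 1], pts[:, 2]]]
    return pts


def neighbor_table(mask: MaskVolume, spec: SearchlightSpec):
    """Flat-index neighbour lists for every mask voxel, for the kernels.

    Returns ``(centers, neigh_flat, neigh_ptr)`` where ``centers`` is the
    (n, 3) array of mask voxel indices and the neighbours of center ``i``
    are ``neigh_flat[neigh_ptr[i]:neigh_ptr[i+1]]`` as C-order flat indices
    into the grid.
    """
    dims = np.asarray(mask.grid.dims)
    centers = mask.indices()
    offs = sphere_offsets(spec.diameter_voxels)
    # (n_centers, n_offsets, 3)
    pts = centers[:, None, :] + offs[None, :, :]
    inb = ((pts >= 0) & (pts < dims)).all(axis=2)
    if spec.restrict_to_mask:
        clipped = np.clip(pts, 0, dims - 1)
        inb &= mask.data[clipped[..., 0], clipped[..., 1], clipped[..., 2]]
    flat_all = (pts[..., 0] * dims[1] + pts[..., 1]) * dims[2] + pts[..., 2]
    counts = inb.sum(axis=1)
    neigh_ptr = np.zeros(len(centers) + 1, dtype=np.int64)
    np.cumsum(counts, out=neigh_ptr[1:])
    neigh_flat = flat_all[inb].astype(np.int64)
    return centers, neigh_flat, neigh_ptr


def gaussian_smooth(volume: np.ndarray, fwhm_mm: float, grid: VoxelGrid) -> np.ndarray:
    """Separable Gaussian smoothing with FWHM given in mm.

    ``fwhm_mm=0`` is the identity.  The boundary is zero-padded, matching
    the zero background the synthetic volumes are embedded in.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    volume = np.asarray(volume, dtype=float)
    if volume.shape != grid.dims:
        raise ValueError("volume shape does not match grid")
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = fwhm_to_sigma(fwhm_mm) / grid.voxel_size_mm
    return ndimage.gaussian_filter(volume, sigma_vox, mode="constant", cval=0.0)


# --------------------------------------------------------------------------
# I/O


def write_nifti(path, volume: np.ndarray, grid: VoxelGrid) -> None:
    """Write a volume as NIfTI-1 (float32 data, the grid's affine)."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a NIfTI volume; returns ``(data, grid)``."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    aff = np.asarray(img.affine, dtype=float)
    vox = float(np.sqrt((aff[:3, 0] ** 2).sum()))
    grid = VoxelGrid(data.shape, voxel_size_mm=vox, affine=aff)
    return data, grid


REQUIRED_COHORT_COLUMNS = ("subject_id", "group")


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (subject_id, group, covariates).

    ``group`` must be ``patient`` or ``control``; a numeric ``label`` column
    (+1 patients, -1 controls) is added.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table {path} missing required columns: {missing}")
    bad = set(df["group"].unique()) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"cohort table {path}: unknown group labels {sorted(bad)}")
    df = df.copy()
    df["label"] = df["group"].map(GROUP_LABELS).astype(int)
    if df["subject_id"].duplicated().any():
        raise ValueError(f"cohort table {path}: duplicate subject_id values")
    return df


def load_subject_stack(
    volume_paths: Sequence, subject_ids: Sequence[str], mask: MaskVolume | None = None
) -> SubjectVolumeStack:
    """Load per-subject NIfTI volumes onto a shared grid."""
    vols = []
    grid = None
    for p in volume_paths:
        data, g = read_nifti(p)
        if grid is None:
            grid = g
        elif not grid.compatible(g):
            raise ValueError(f"volume {p} has mismatched dims/affine")
        vols.append(data)
    if grid is None:
        raise ValueError("no volumes given")
    return SubjectVolumeStack(grid, list(subject_ids), np.stack(vols), mask)
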