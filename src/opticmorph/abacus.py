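"""3D nuclear counting on confocal z-stacks.

The counting pipeline detects fluorescently labeled nuclei in an
anisotropically sampled volume (in-plane pixel size ``dx``, z-step ``dz``)
as the extended maxima of a smoothed intensity field:

1. linear Hi-Lo rescaling so background maps to 0 and the chosen ceiling
   maps to just below the bit-depth maximum,
2. 3D Gaussian low-pass with per-axis standard deviations
   (sigma_xy, sigma_xy, sigma_z) in voxel units, where
   ``sigma_z = sigma_xy * dx / dz`` so the physical smoothing scale is
   isotropic,
3. a gray-value noise threshold ``L`` (voxels below L are zeroed),
4. the h-maxima transform (grayscale reconstruction of image - h under
   the image) followed by regional-maxima extraction, suppressing peaks
   whose dynamic is below ``h``,
5. connected-component labeling of the extended-maxima mask and
   unweighted centroid extraction, converted to physical µm coordinates.

Each connected plateau yields exactly one centroid; no peak splitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

__all__ = [
    "VoxelGrid",
    "AbacusParams",
    "CentroidSet",
    "rescale_hi_lo",
    "smooth_anisotropic",
    "extended_maxima",
    "find_nuclei",
    "count_in_roi",
]

# scikit-image connectivity rank (max orthogonal steps per hop) for the
# three standard 3D voxel neighborhoods
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Gray values, z-major plane order.
    dx : float
        In-plane pixel size in µm (isotropic in xy).
    dz : float
        z-step in µm.
    bit_depth : int
        Nominal bit depth (8 or 16); bounds the admissible gray range.
    """

    data: np.ndarray
    dx: float
    dz: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError("data must be a 3D array with nonempty axes")
        if self.dx <= 0 or self.dz <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        vmax = 2**self.bit_depth - 1
        if data.size and (data.min() < 0 or data.max() > vmax):
            raise ValueError(f"gray values outside [0, {vmax}]")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def vmax(self) -> int:
        return 2**self.bit_depth - 1

    def sigma_z_for(self, sigma_xy: float) -> float:
        """Derived z-axis smoothing scale: sigma_xy * dx / dz (voxel units)."""
        return sigma_xy * self.dx / self.dz


@dataclass(frozen=True)
class AbacusParams:
    """Tunables of the counting pipeline.

    sigma_xy is expressed in xy-voxel units; the z sigma is always derived
    from the grid it is applied to as ``sigma_xy * dx / dz``. L and h are
    gray values on the rescaled image. In practice these are tuned per
    dataset by overlaying detected centroids on intensity isosurfaces; the
    defaults here suit nuclei ~5-10 px across in xy.
    """

    sigma_xy: float = 3.0
    L: float = 12.0
    h: float = 8.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.sigma_xy <= 0:
            raise ValueError("sigma_xy must be positive")
        if self.L < 0:
            raise ValueError("L must be nonnegative")
        if self.h <= 0:
            raise ValueError("h must be positive")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class CentroidSet:
    """Detected nucleus centroids in physical coordinates.

    points holds (x, y, z) µm triples; peak_values the gray value attained
    within each maxima region.
    """

    points: np.ndarray
    peak_values: np.ndarray
    source_shape: tuple[int, int, int] = (0, 0, 0)
    dx: float = 1.0
    dz: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.peak_values = np.asarray(self.peak_values, dtype=float).ravel()
        if len(self.points) != len(self.peak_values):
            raise ValueError("points and peak_values disagree in length")

    @property
    def count(self) -> int:
        return len(self.points)


def rescale_hi_lo(grid: VoxelGrid, background: float, ceiling: float) -> VoxelGrid:
    """Linear Hi-Lo rescaling: background → 0, ceiling → vmax - 1.

    Mimics adjusting the display range with a Hi-Lo lookup table so the
    background noise level sits at zero and the brightest pixels just
    below the bit-depth maximum (254 for 8-bit). Values are clipped at
    both ends and floored to integers.
    """
    if background >= ceiling:
        raise ValueError("background must be below ceiling")
    if ceiling > grid.vmax:
        raise ValueError(f"ceiling exceeds bit-depth maximum {grid.vmax}")
    top = grid.vmax - 1
    scaled = (grid.data.astype(float) - background) * (top / (ceiling - background))
    out = np.floor(np.clip(scaled, 0, top))
    dtype = np.uint8 if grid.bit_depth == 8 else np.uint16
    return VoxelGrid(out.astype(dtype), grid.dx, grid.dz, grid.bit_depth)


def smooth_anisotropic(grid: VoxelGrid, sigma_xy: float) -> VoxelGrid:
    """Gaussian low-pass with physically isotropic smoothing.

    Per-axis standard deviations are (sigma_z, sigma_xy, sigma_xy) in
    voxel units for (z, y, x) data, with sigma_z = sigma_xy * dx / dz.
    Boundaries are handled by reflection, which conserves total intensity.
    """
    if sigma_xy <= 0:
        raise ValueError("sigma_xy must be positive")
    sigma_z = grid.sigma_z_for(sigma_xy)
    out = ndimage.gaussian_filter(
        grid.data.astype(float), sigma=(sigma_z, sigma_xy, sigma_xy), mode="reflect"
    )
    # reflection + clipping keeps values inside the original gray range
    out = np.clip(out, 0, grid.vmax)
    return VoxelGrid(out, grid.dx, grid.dz, grid.bit_depth)


def extended_maxima(image: np.ndarray, h: float, connectivity: int = 26) -> np.ndarray:
    """Label the extended-maxima regions of a 3D image.

    The h-maxima transform (grayscale reconstruction by dilation of
    image - h under image) suppresses every regional maximum whose dynamic
    is below h; the regional maxima of the reconstructed image are the
    surviving peaks. Returns an integer label volume where each connected
    maxima plateau carries one positive label.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    rank = _CONNECTIVITY_RANK[connectivity]
    image = np.asarray(image, dtype=float)
    rec = morphology.reconstruction(
        image - h, image, method="dilation",
        footprint=ndimage.generate_binary_structure(3, rank),
    )
    mask = morphology.local_maxima(rec, connectivity=rank, allow_borders=True)
    structure = ndimage.generate_binary_structure(3, rank)
    labels, _ = ndimage.label(mask, structure=structure)
    return labels


def find_nuclei(grid: VoxelGrid, params: AbacusParams) -> CentroidSet:
    """Detect nuclei as extended maxima of the smoothed, thresholded stack.

    Returns an empty CentroidSet (not an error) when nothing survives the
    threshold, and warns when h exceeds the dynamic range left after
    thresholding.
    """
    empty = CentroidSet(
        np.empty((0, 3)), np.empty(0), grid.shape, grid.dx, grid.dz
    )
    smoothed = smooth_anisotropic(grid, params.sigma_xy).data
    smoothed = np.where(smoothed < params.L, 0.0, smoothed)
    if not smoothed.any():
        return empty
    dynamic = float(smoothed.max() - smoothed.min())
    if params.h >= dynamic:
        warnings.warn(
            f"h={params.h} is at or above the post-threshold dynamic range "
            f"({dynamic:.3g}); no maxima can survive", stacklevel=2,
        )
        return empty
    labels = extended_maxima(smoothed, params.h, params.connectivity)
    n = labels.max()
    if n == 0:
        return empty
    # unweighted region centroid, voxel indices (z, y, x)
    centers = ndimage.center_of_mass(np.ones_like(labels), labels, range(1, n + 1))
    peaks = ndimage.labeled_comprehension(
        smoothed, labels, range(1, n + 1), np.max, float, 0.0
    )
    centers = np.asarray(centers, dtype=float)
    points = np.column_stack(
        [centers[:, 2] * grid.dx, centers[:, 1] * grid.dx, centers[:, 0] * grid.dz]
    )
    return CentroidSet(points, peaks, grid.shape, grid.dx, grid.dz)


def _nearest_voxels(centroids: CentroidSet, shape: tuple[int, int, int]) -> np.ndarray:
    """(z, y, x) index of the voxel nearest each centroid, clipped to bounds."""
    iz = np.rint(centroids.points[:, 2] / centroids.dz).astype(int)
    iy = np.rint(centroids.points[:, 1] / centroids.dx).astype(int)
    ix = np.rint(centroids.points[:, 0] / centroids.dx).astype(int)
    idx = np.column_stack([iz, iy, ix])
    return np.clip(idx, 0, np.array(shape) - 1)


def count_in_roi(centroids: CentroidSet, roi: np.ndarray) -> int:
    """Count centroids whose nearest voxel falls inside a binary ROI."""
    roi = np.asarray(roi).astype(bool)
    if centroids.count and roi.shape != tuple(centroids.source_shape):
        raise ValueError(
            f"ROI shape {roi.shape} does not match grid {centroids.source_shape}"
        )
    if centroids.count == 0:
        return 0
    idx = _nearest_voxels(centroids, roi.shape)
    return int(roi[idx[:, 0], idx[:, 1], idx[:, 2]].sum())


def roi_membership(centroids: CentroidSet, roi: np.ndarray) -> np.ndarray:
    """Boolean mask over centroids: nearest voxel inside the ROI."""
    roi = np.asarray(roi).astype(bool)
    if centroids.count == 0:
        return np.zeros(0, dtype=bool)
    if roi.shape != tuple(centroids.source_shape):
        raise ValueError("ROI shape does not match the source grid")
    idx = _nearest_voxels(centroids, roi.shape)
    return roi[idx[:, 0], idx[:, 1], idx[:, 2]]
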