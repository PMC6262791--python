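"""Cell and tissue morphometry: shape, angle, extent, profile and volume.

Shape descriptors follow the Fiji/ImageJ conventions the measurements were
defined with: roundness is 4*Area / (pi * major_axis^2) with the major axis
taken from an ellipse fitted by second-order central moments (1.0 for a
circle, approaching 0 for a needle), and a cell's elongation angle is the
axial angle between that fitted long axis and the embryo's
anterior-posterior (AP) axis, folded into [-90, 90) degrees.

Coordinates are 0-based pixel centers; 2D masks are row-major (y, x) and
3D grids (z, y, x). Angles are measured in image coordinates (y pointing
down), positive rotating from the AP axis toward +y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegionMask2D",
    "AngleMeasurement",
    "ProfileConfig",
    "ExtentMeasurement",
    "IntensityRatio",
    "roundness",
    "elongation_angle",
    "fissure_angle",
    "ap_extent_fraction",
    "reporter_midpoint_fraction",
    "quarter_intensity_ratio",
    "label_volumes",
]


@dataclass(frozen=True)
class RegionMask2D:
    """Binary outline mask of one cell or ROI with physical pixel size and
    the embryo AP-axis direction in image coordinates."""

    mask: np.ndarray
    pixel_size: float = 1.0
    ap_axis: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask).astype(bool)
        if mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not mask.any():
            raise ValueError("mask is empty")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        ap = np.asarray(self.ap_axis, dtype=float)
        norm = np.linalg.norm(ap)
        if norm == 0:
            raise ValueError("ap_axis must be a nonzero vector")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "ap_axis", tuple(ap / norm))

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class AngleMeasurement:
    """An angle in degrees; axis_stable is False when the measured region is
    too round for its long axis to be meaningful."""

    degrees: float
    axis_stable: bool = True


@dataclass(frozen=True)
class ProfileConfig:
    """Rectangular-ROI profile settings: the rectangle is rect_width_px wide
    (44 px at this acquisition scale, i.e. 30.44 µm) and the AP profile is
    split into four equal quarters."""

    rect_width_px: int = 44

    def __post_init__(self) -> None:
        if self.rect_width_px < 1:
            raise ValueError("rect_width_px must be >= 1")


@dataclass(frozen=True)
class ExtentMeasurement:
    expression_extent: float
    vesicle_length: float
    fraction: float


@dataclass(frozen=True)
class IntensityRatio:
    """Anterior/posterior quarter intensity ratio; defined is False when the
    posterior quarter has zero mean intensity."""

    ratio: float
    anterior_mean: float
    posterior_mean: float
    defined: bool = True


def _central_second_moments(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Covariance matrix of pixel coordinates (x, y) and the centroid."""
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    centroid = pts.mean(axis=0)
    d = pts - centroid
    cov = d.T @ d / len(pts)
    return cov, centroid


def _fitted_axes(mask: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Major/minor full axis lengths (px) and the major-axis unit vector of
    the moment-fitted ellipse (the ellipse with matching second moments)."""
    cov, _ = _central_second_moments(mask)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    # ellipse with the same normalized second moments: full axis = 4 sqrt(λ)
    minor = 4.0 * np.sqrt(max(evals[0], 0.0))
    major = 4.0 * np.sqrt(max(evals[1], 0.0))
    return major, minor, evecs[:, 1]


def roundness(region: RegionMask2D) -> float:
    """Fiji shape-descriptor roundness: 4*Area / (pi * major_axis^2).

    Area is the pixel count and major_axis the full major diameter of the
    moment-fitted ellipse, both in pixel units. The result is clipped at
    1.0, where rasterization can push a near-circle slightly above.
    """
    if region.area_px < 5:
        raise ValueError("region too small (need >= 5 px)")
    major, minor, _ = _fitted_axes(region.mask)
    if minor == 0.0:
        raise ValueError("degenerate (collinear) region: no fitted ellipse")
    value = 4.0 * region.area_px / (np.pi * major**2)
    return float(min(value, 1.0))


def _fold_axial(angle_deg: float) -> float:
    return float((angle_deg + 90.0) % 180.0 - 90.0)


_ROUNDNESS_STABLE_LIMIT = 0.95


def elongation_angle(region: RegionMask2D) -> AngleMeasurement:
    """Axial angle between the cell's fitted long axis and the AP axis.

    Folded into [-90, 90) degrees since cell orientation is axial (a cell
    at 120 degrees is the same cell as one at -60). Near-circular regions
    (roundness >= 0.95) are flagged unstable rather than rejected.
    """
    r = roundness(region)
    major, minor, v = _fitted_axes(region.mask)
    ax, ay = region.ap_axis
    angle = np.degrees(np.arctan2(ax * v[1] - ay * v[0], ax * v[0] + ay * v[1]))
    return AngleMeasurement(_fold_axial(angle), axis_stable=r < _ROUNDNESS_STABLE_LIMIT)


def fissure_angle(
    vertex: tuple[float, float],
    ray_point_1: tuple[float, float],
    ray_point_2: tuple[float, float],
) -> AngleMeasurement:
    """Opening angle between two rays from a common vertex, in degrees.

    Measures the optic fissure opening on a lateral-view projection: the
    vertex sits at the lens center and the rays run along the fissure
    margins. The interior angle lies in (0, 180].
    """
    v = np.asarray(vertex, dtype=float)
    r1 = np.asarray(ray_point_1, dtype=float) - v
    r2 = np.asarray(ray_point_2, dtype=float) - v
    n1, n2 = np.linalg.norm(r1), np.linalg.norm(r2)
    if n1 == 0 or n2 == 0:
        raise ValueError("ray points must be distinct from the vertex")
    cosang = np.clip(np.dot(r1, r2) / (n1 * n2), -1.0, 1.0)
    return AngleMeasurement(float(np.degrees(np.arccos(cosang))))


def ap_extent_fraction(
    expression_interval: tuple[float, float], vesicle_interval: tuple[float, float]
) -> ExtentMeasurement:
    """Fraction of the optic vesicle's AP length occupied by an expression
    domain, both given as (start, end) intervals along the AP axis."""
    e0, e1 = expression_interval
    v0, v1 = vesicle_interval
    if e1 < e0 or v1 < v0:
        raise ValueError("intervals must have start <= end")
    if v1 == v0:
        raise ValueError("vesicle interval has zero length")
    extent = e1 - e0
    length = v1 - v0
    return ExtentMeasurement(extent, length, extent / length)


def reporter_midpoint_fraction(
    medial_extent: float, lateral_extent: float, vesicle_length: float
) -> float:
    """AP midpoint of reporter expression as a ratio of vesicle length.

    The medial and lateral AP extents of the expression trail are averaged
    and normalized by the full optic-vesicle length.
    """
    if medial_extent < 0 or lateral_extent < 0:
        raise ValueError("extents must be nonnegative")
    if vesicle_length <= 0:
        raise ValueError("vesicle_length must be positive")
    return float((medial_extent + lateral_extent) / 2.0 / vesicle_length)


def quarter_intensity_ratio(
    image: np.ndarray,
    rect: tuple[int, int, int, int],
    cfg: ProfileConfig = ProfileConfig(),
) -> IntensityRatio:
    """Anterior/posterior quarter ratio of a rectangular-ROI plot profile.

    The rectangle (x0, y0, width, height) must lie inside the image with
    rows running along the AP axis (anterior at low row index, the image
    pre-rotated so the vesicle is vertical). The per-row mean across the
    rectangle width gives the profile; rows are split into four quarters of
    floor(n/4) rows each, remainder rows assigned to the middle, and the
    ratio is mean(anterior quarter) / mean(posterior quarter).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    x0, y0, w, h = rect
    ny, nx = img.shape
    if w < 1 or h < 4:
        raise ValueError("rectangle must be >= 1 px wide and >= 4 px long")
    if x0 < 0 or y0 < 0 or x0 + w > nx or y0 + h > ny:
        raise ValueError("rectangle extends outside the image")
    profile = img[y0 : y0 + h, x0 : x0 + w].mean(axis=1)
    q = h // 4
    anterior = float(profile[:q].mean())
    posterior = float(profile[-q:].mean())
    if posterior == 0.0:
        return IntensityRatio(float("nan"), anterior, posterior, defined=False)
    return IntensityRatio(anterior / posterior, anterior, posterior)


def label_volumes(labeled: np.ndarray, dx: float, dz: float) -> pd.DataFrame:
    """Physical volume per label of a 3D segmentation, in µm³.

    volume(label) = voxel count * dx² * dz; the relative column gives each
    label's share of the total nonbackground volume (label 0 = background),
    e.g. V_stalk / (V_cup + V_stalk) for a two-label cup/stalk grid.
    """
    labeled = np.asarray(labeled)
    if labeled.ndim != 3:
        raise ValueError("labeled grid must be 3D")
    if labeled.min() < 0:
        raise ValueError("labels must be nonnegative")
    if dx <= 0 or dz <= 0:
        raise ValueError("spacing must be positive")
    counts = np.bincount(labeled.ravel())
    labels = np.nonzero(counts)[0]
    labels = labels[labels > 0]
    voxel = dx * dx * dz
    volumes = counts[labels] * voxel
    total = volumes.sum()
    return pd.DataFrame(
        {
            "label": labels.astype(int),
            "n_voxels": counts[labels].astype(int),
            "volume_um3": volumes,
            "relative": volumes / total if total > 0 else volumes,
        }
    )
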