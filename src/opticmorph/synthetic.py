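"""Synthetic ground-truth generators for every pipeline input.

Emulates the data the quantification layer consumes: anisotropic two-channel
confocal stacks of blob-like nuclei, elongated-cell outlines at controlled
orientations, piecewise-smooth 3D trajectories sampled at a fixed frame
interval, and labeled tissue volumes. Every generator is seeded and
deterministic, and returns the planted truth alongside the rendered data.

Nuclei are rendered as isotropic 3D Gaussians in physical units, sampled on
the anisotropic voxel grid and corrupted with additive, clipped Gaussian
noise. The defaults mirror a 40x confocal acquisition: 512x512 planes at
0.692 µm pixels, 2.1 µm z-steps, 8-bit gray levels, and 2.75 min between
z-stacks for time-lapse data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .abacus import VoxelGrid
from .morphometry import RegionMask2D
from .tracking import Trajectory

__all__ = [
    "NucleusSpec",
    "SyntheticVolumeTruth",
    "SyntheticTrajectoryTruth",
    "EllipseTruth",
    "make_nuclei_volume",
    "make_ellipse_mask",
    "make_trajectory",
    "make_labeled_volume",
    "random_well_separated_nuclei",
    "DEFAULT_DX",
    "DEFAULT_DZ",
    "DEFAULT_SHAPE",
    "FRAME_INTERVAL_MIN",
]

DEFAULT_DX = 0.692   # µm, in-plane pixel size
DEFAULT_DZ = 2.1     # µm, z-step
DEFAULT_SHAPE = (60, 512, 512)  # (nz, ny, nx)
FRAME_INTERVAL_MIN = 2.75  # minutes between z-stacks in time-lapse data

_CHANNELS = ("green", "red")


@dataclass(frozen=True)
class NucleusSpec:
    """One planted nucleus: physical center (µm), isotropic intensity
    spread sigma (µm), peak amplitude (gray value) and channel."""

    center: tuple[float, float, float]  # (x, y, z) µm
    sigma: float
    amplitude: float
    channel: str = "green"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {_CHANNELS}")


@dataclass(frozen=True)
class SyntheticVolumeTruth:
    """Planted scene for a two-channel nuclear stack."""

    nuclei: tuple[NucleusSpec, ...]
    dx: float = DEFAULT_DX
    dz: float = DEFAULT_DZ
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nuclei", tuple(self.nuclei))
        if self.dx <= 0 or self.dz <= 0:
            raise ValueError("spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def centers(self, channel: str | None = None) -> np.ndarray:
        """(n, 3) array of planted centers (x, y, z) µm, optionally per channel."""
        sel = [
            n.center for n in self.nuclei
            if channel is None or n.channel == channel
        ]
        return np.asarray(sel, dtype=float).reshape(-1, 3)


def make_nuclei_volume(
    truth: SyntheticVolumeTruth, shape: tuple[int, int, int]
) -> dict[str, VoxelGrid]:
    """Render the planted nuclei into one 8-bit grid per channel present.

    Each nucleus contributes amplitude * exp(-r^2 / (2 sigma^2)) with r the
    physical distance to its center; channels are rendered independently
    (no bleed-through). Zero-mean Gaussian noise of sd noise_sd is added,
    then values are clipped to [0, 255] and rounded. Identical truth and
    shape give bit-identical output.
    """
    nz, ny, nx = shape
    if min(shape) < 1:
        raise ValueError("shape must be positive in every axis")
    extent = np.array([(nx - 1) * truth.dx, (ny - 1) * truth.dx, (nz - 1) * truth.dz])
    for i, nuc in enumerate(truth.nuclei):
        c = np.asarray(nuc.center, dtype=float)
        if (c < 0).any() or (c > extent).any():
            raise ValueError(
                f"nucleus {i} at {tuple(c)} lies outside the volume bounds "
                f"(extent {tuple(extent)})"
            )

    channels = sorted({n.channel for n in truth.nuclei}) or ["green"]
    fields = {ch: np.zeros(shape, dtype=float) for ch in channels}
    zs = np.arange(nz) * truth.dz
    ys = np.arange(ny) * truth.dx
    xs = np.arange(nx) * truth.dx
    for nuc in truth.nuclei:
        cx, cy, cz = nuc.center
        # render only within ±4.5 sigma of the center
        r = 4.5 * nuc.sigma
        iz = slice(
            int(np.searchsorted(zs, cz - r)), int(np.searchsorted(zs, cz + r, "right"))
        )
        iy = slice(
            int(np.searchsorted(ys, cy - r)), int(np.searchsorted(ys, cy + r, "right"))
        )
        ix = slice(
            int(np.searchsorted(xs, cx - r)), int(np.searchsorted(xs, cx + r, "right"))
        )
        dz2 = (zs[iz] - cz) ** 2
        dy2 = (ys[iy] - cy) ** 2
        dx2 = (xs[ix] - cx) ** 2
        r2 = dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
        fields[nuc.channel][iz, iy, ix] += nuc.amplitude * np.exp(
            -r2 / (2 * nuc.sigma**2)
        )

    rng = np.random.default_rng(truth.seed)
    out: dict[str, VoxelGrid] = {}
    for ch in channels:  # fixed (sorted) order keeps the noise stream reproducible
        data = fields[ch]
        if truth.noise_sd > 0:
            data = data + rng.normal(0.0, truth.noise_sd, size=shape)
        data = np.rint(np.clip(data, 0, 255)).astype(np.uint8)
        out[ch] = VoxelGrid(data, truth.dx, truth.dz, bit_depth=8)
    return out


def random_well_separated_nuclei(
    n: int,
    shape: tuple[int, int, int],
    *,
    dx: float = DEFAULT_DX,
    dz: float = DEFAULT_DZ,
    sigma: float = 1.8,
    min_separation: float | None = None,
    amplitude: tuple[float, float] = (160.0, 230.0),
    green_fraction: float = 1.0,
    seed: int = 0,
    max_tries: int = 200_000,
) -> SyntheticVolumeTruth:
    """Plant n nuclei with pairwise center distance above a separation floor.

    Separation defaults to 6.5*sigma, comfortably above the merge distance
    of the counting pipeline's smoothing scale. Centers keep a 3.5*sigma
    margin from the physical borders so no blob is clipped. Channel
    assignment is Bernoulli(green_fraction) but the requested green count
    is enforced exactly by assigning the first round(n*green_fraction)
    shuffled nuclei to green.
    """
    nz, ny, nx = shape
    sep = 6.5 * sigma if min_separation is None else min_separation
    margin = 3.5 * sigma
    lo = np.array([margin, margin, margin])
    hi = np.array([(nx - 1) * dx - margin, (ny - 1) * dx - margin, (nz - 1) * dz - margin])
    if (hi <= lo).any():
        raise ValueError("volume too small for the requested margin")
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place all nuclei at this separation")
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - c) > sep for c in centers):
            centers.append(cand)
    amps = rng.uniform(*amplitude, size=n)
    n_green = int(round(n * green_fraction))
    order = rng.permutation(n)
    channel = np.array(["red"] * n, dtype=object)
    channel[order[:n_green]] = "green"
    nuclei = [
        NucleusSpec(tuple(c), sigma, float(a), str(ch))
        for c, a, ch in zip(centers, amps, channel)
    ]
    return SyntheticVolumeTruth(tuple(nuclei), dx, dz, seed=seed)


@dataclass(frozen=True)
class EllipseTruth:
    """A rasterized elongated-cell outline plus its planted descriptors."""

    region: RegionMask2D
    true_roundness: float
    true_angle_deg: float


def fold_axial(angle_deg: float) -> float:
    """Fold an axial angle into [-90, 90) degrees (180-degree symmetry)."""
    return float((angle_deg + 90.0) % 180.0 - 90.0)


def make_ellipse_mask(
    major: float,
    minor: float,
    angle_deg: float,
    pixel_size: float,
    shape: tuple[int, int],
    *,
    center: tuple[float, float] | None = None,
    ap_axis: tuple[float, float] = (1.0, 0.0),
) -> EllipseTruth:
    """Rasterize a filled rotated ellipse as a cell-outline mask.

    major/minor are full axis lengths in µm; angle_deg is the major-axis
    orientation relative to the AP axis, in image coordinates (y down).
    True roundness is minor/major; the true angle is folded into the axial
    range [-90, 90).
    """
    if not (major >= minor > 0):
        raise ValueError("require major >= minor > 0")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    ny, nx = shape
    a = major / (2 * pixel_size)
    b = minor / (2 * pixel_size)
    cy, cx = ((ny - 1) / 2, (nx - 1) / 2) if center is None else center
    theta = np.radians(angle_deg)
    ux, uy = np.cos(theta), np.sin(theta)
    # analytic half-extents of the rotated ellipse along image axes
    ext_x = np.hypot(a * ux, b * uy)
    ext_y = np.hypot(a * uy, b * ux)
    if (cx - ext_x < 1) or (cx + ext_x > nx - 2) or (cy - ext_y < 1) or (cy + ext_y > ny - 2):
        raise ValueError("ellipse is clipped by the image border")
    yy, xx = np.mgrid[0:ny, 0:nx]
    px = xx - cx
    py = yy - cy
    u = px * ux + py * uy
    v = -px * uy + py * ux
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    region = RegionMask2D(mask, pixel_size=pixel_size, ap_axis=ap_axis)
    return EllipseTruth(region, minor / major, fold_axial(angle_deg))


@dataclass(frozen=True)
class SyntheticTrajectoryTruth:
    """Waypoint polyline defining one planted cell track.

    true_path_length and true_net_displacement are derived from the
    waypoints on construction; dt defaults to the 2.75 min frame interval.
    """

    waypoints: tuple[tuple[float, float, float], ...]
    dt: float = FRAME_INTERVAL_MIN
    noise_sd: float = 0.0
    seed: int = 0
    true_path_length: float = field(init=False)
    true_net_displacement: float = field(init=False)

    def __post_init__(self) -> None:
        wp = np.asarray(self.waypoints, dtype=float).reshape(-1, 3)
        if len(wp) < 2:
            raise ValueError("need at least two waypoints")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "waypoints", tuple(map(tuple, wp)))
        seg = np.linalg.norm(np.diff(wp, axis=0), axis=1)
        object.__setattr__(self, "true_path_length", float(seg.sum()))
        object.__setattr__(
            self, "true_net_displacement", float(np.linalg.norm(wp[-1] - wp[0]))
        )


def make_trajectory(
    truth: SyntheticTrajectoryTruth, n_samples: int, track_id: str = "synthetic"
) -> Trajectory:
    """Sample the waypoint polyline at constant speed with optional jitter.

    Points are taken at equal arclength increments (constant speed along
    the polyline), Gaussian positional jitter of sd noise_sd is added, and
    timestamps are multiples of dt.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    wp = np.asarray(truth.waypoints, dtype=float)
    seg = np.linalg.norm(np.diff(wp, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_query = np.linspace(0.0, s[-1], n_samples)
    xyz = np.column_stack([np.interp(s_query, s, wp[:, k]) for k in range(3)])
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        xyz = xyz + rng.normal(0.0, truth.noise_sd, size=xyz.shape)
    t = np.arange(n_samples) * truth.dt
    return Trajectory(track_id=track_id, t=t, xyz=xyz)


def make_labeled_volume(
    regions: list[tuple[int, np.ndarray]],
    shape: tuple[int, int, int],
    dx: float = DEFAULT_DX,
    dz: float = DEFAULT_DZ,
) -> tuple[np.ndarray, dict[int, float]]:
    """Build a labeled tissue volume from disjoint voxel sets.

    regions is a list of (label, voxel indices) with indices shaped (n, 3)
    in (z, y, x) order. Returns the label grid and the true physical volume
    per label (voxel count x dx^2 x dz, in µm^3). Overlapping regions or
    nonpositive labels are rejected.
    """
    labeled = np.zeros(shape, dtype=np.int32)
    truth: dict[int, float] = {}
    voxel = dx * dx * dz
    for label, vox in regions:
        if label <= 0:
            raise ValueError("labels must be positive integers")
        if label in truth:
            raise ValueError(f"duplicate label {label}")
        vox = np.asarray(vox, dtype=int).reshape(-1, 3)
        z, y, x = vox[:, 0], vox[:, 1], vox[:, 2]
        if (labeled[z, y, x] != 0).any():
            raise ValueError(f"label {label} overlaps a previous region")
        labeled[z, y, x] = label
        truth[label] = len(vox) * voxel
    return labeled, truth
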