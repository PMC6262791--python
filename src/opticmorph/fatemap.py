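"""Photoconversion fate-map quantification.

In a Kaede fate map, photoconverted nuclei fluoresce red while unconverted
nuclei remain green; the quantity of interest is the proportion of green
(unconverted) nuclei among all nuclei inside a region of interest such as
the optic cup. Nuclei are detected per channel with the 3D counting
pipeline, restricted to the ROI, and the total is either taken from a
dedicated all-nuclei channel or built as the green/red union with
double-positive suppression: a green centroid within one nuclear radius of
a red centroid is a partially converted nucleus and counts once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .abacus import AbacusParams, CentroidSet, VoxelGrid, find_nuclei, roi_membership

__all__ = ["FateMapResult", "marked_fraction", "marked_fraction_union"]

#: default matching radius for double-positive suppression, µm
#: (a typical nuclear radius at this imaging scale)
DEFAULT_MATCH_RADIUS_UM = 3.0


@dataclass(frozen=True)
class FateMapResult:
    """Green-nucleus proportion in an ROI; defined is False when no nuclei
    were found at all (the fraction is then meaningless, not silently 0)."""

    n_green: int
    n_total: int
    fraction: float
    defined: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.n_green <= self.n_total):
            raise ValueError("require 0 <= n_green <= n_total")


def _roi_points(grid: VoxelGrid, params: AbacusParams, roi: np.ndarray) -> np.ndarray:
    found = find_nuclei(grid, params)
    if found.count == 0:
        return np.empty((0, 3))
    return found.points[roi_membership(found, roi)]


def _check_congruent(*grids: VoxelGrid, roi: np.ndarray) -> None:
    shapes = {g.shape for g in grids} | {np.asarray(roi).shape}
    if len(shapes) != 1:
        raise ValueError(f"channels and ROI must be congruent; got shapes {shapes}")


def marked_fraction(
    green_channel: VoxelGrid,
    all_nuclei_channel: VoxelGrid,
    params_green: AbacusParams,
    params_all: AbacusParams,
    roi: np.ndarray,
) -> FateMapResult:
    """Green fraction with the total from a dedicated all-nuclei channel
    (e.g. a nuclear counterstain): green count / total count, both
    restricted to the ROI."""
    _check_congruent(green_channel, all_nuclei_channel, roi=roi)
    n_green = len(_roi_points(green_channel, params_green, roi))
    n_total = len(_roi_points(all_nuclei_channel, params_all, roi))
    if n_total == 0:
        return FateMapResult(0, 0, float("nan"), defined=False)
    return FateMapResult(n_green, n_total, n_green / n_total)


def marked_fraction_union(
    green_channel: VoxelGrid,
    red_channel: VoxelGrid,
    params_green: AbacusParams,
    params_red: AbacusParams,
    roi: np.ndarray,
    match_radius: float = DEFAULT_MATCH_RADIUS_UM,
) -> FateMapResult:
    """Green fraction with the total built as the green/red union.

    total = n_green + n_red - (double positives), where a double positive
    is a green centroid lying within match_radius (µm) of some red
    centroid. Suitable for the standard Kaede scheme where no separate
    counterstain exists.
    """
    _check_congruent(green_channel, red_channel, roi=roi)
    green = _roi_points(green_channel, params_green, roi)
    red = _roi_points(red_channel, params_red, roi)
    n_green, n_red = len(green), len(red)
    if n_green + n_red == 0:
        return FateMapResult(0, 0, float("nan"), defined=False)
    n_double = 0
    if n_green and n_red and match_radius > 0:
        tree = cKDTree(red)
        dist, _ = tree.query(green, distance_upper_bound=match_radius)
        n_double = int(np.isfinite(dist).sum())
    n_total = n_green + n_red - n_double
    return FateMapResult(n_green, n_total, n_green / n_total)
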