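"""File I/O: TIFF stacks, truth sidecars, centroid and trajectory tables.

Volumes are stored as single-channel TIFFs in z-major plane order with the
voxel spacing supplied out of band (CLI flags, YAML config, or a JSON
sidecar written next to synthetic volumes). Tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .abacus import CentroidSet, VoxelGrid
from .tracking import Trajectory

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "centroids_to_frame",
    "save_centroids",
    "save_truth_sidecar",
    "save_trajectories",
]


def save_volume(path, grid: VoxelGrid) -> None:
    dtype = np.uint8 if grid.bit_depth == 8 else np.uint16
    tifffile.imwrite(str(path), np.asarray(grid.data).astype(dtype))


def load_volume(path, dx: float, dz: float, bit_depth: int = 8) -> VoxelGrid:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return VoxelGrid(data, dx, dz, bit_depth)


def save_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def load_mask(path) -> np.ndarray:
    return tifffile.imread(str(path)) > 0


def centroids_to_frame(cs: CentroidSet) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_um": cs.points[:, 0],
            "y_um": cs.points[:, 1],
            "z_um": cs.points[:, 2],
            "peak": cs.peak_values,
        }
    )


def save_centroids(path, cs: CentroidSet) -> None:
    centroids_to_frame(cs).to_csv(path, index=False)


def save_truth_sidecar(path, truth) -> None:
    """JSON sidecar for a synthetic volume: planted nuclei, spacing, seed."""
    payload = {
        "dx_um": truth.dx,
        "dz_um": truth.dz,
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "nuclei": [
            {
                "center_um": list(n.center),
                "sigma_um": n.sigma,
                "amplitude": n.amplitude,
                "channel": n.channel,
            }
            for n in truth.nuclei
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def save_trajectories(path, trajectories: list[Trajectory]) -> None:
    frames = []
    for traj in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": traj.track_id,
                    "t_min": traj.t,
                    "x_um": traj.xyz[:, 0],
                    "y_um": traj.xyz[:, 1],
                    "z_um": traj.xyz[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
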