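"""Trajectory kinematics and tracking quality control.

Operates on tables of manually tracked nuclear centroids sampled at a
uniform frame interval. Three metrics summarize each track in 3D physical
coordinates: total path length, net displacement (straight-line distance
from first to last position), and average speed (path length divided by
elapsed time, which equals the mean framewise speed under uniform dt).
A pixel-overlap check implements the acceptance rule used during manual
tracking: consecutive nuclear masks must share at least 50% of the
smaller mask's pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrackMetrics",
    "track_metrics",
    "overlap_ok",
    "group_summary",
    "read_tracks",
    "metrics_table",
]


@dataclass(frozen=True)
class Trajectory:
    """One tracked cell: timestamps (min) and positions (µm).

    Timestamps must be strictly increasing and uniformly spaced to within
    1%; tracks with gaps are rejected rather than interpolated, since the
    manual tracking workflow they come from is gap-free by construction.
    """

    track_id: str
    t: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float).ravel()
        xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if len(t) < 2:
            raise ValueError(f"track {self.track_id}: need at least 2 samples")
        if len(t) != len(xyz):
            raise ValueError(f"track {self.track_id}: t and xyz disagree in length")
        steps = np.diff(t)
        if (steps <= 0).any():
            raise ValueError(f"track {self.track_id}: timestamps must increase")
        dt = steps.mean()
        if np.abs(steps - dt).max() > 0.01 * dt:
            raise ValueError(
                f"track {self.track_id}: non-uniform sampling (gap or jitter "
                f"beyond 1% of dt={dt:.4g} min); gapped tracks are rejected"
            )
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xyz", xyz)

    @property
    def dt(self) -> float:
        return float(np.diff(self.t).mean())


@dataclass(frozen=True)
class TrackMetrics:
    track_id: str
    avg_speed: float        # µm/min
    path_length: float      # µm
    net_displacement: float  # µm


def track_metrics(traj: Trajectory) -> TrackMetrics:
    """3D path length, net displacement and average speed of one track."""
    steps = np.linalg.norm(np.diff(traj.xyz, axis=0), axis=1)
    path = float(steps.sum())
    net = float(np.linalg.norm(traj.xyz[-1] - traj.xyz[0]))
    elapsed = float(traj.t[-1] - traj.t[0])
    return TrackMetrics(traj.track_id, path / elapsed, path, net)


def overlap_ok(
    mask_t: np.ndarray, mask_t1: np.ndarray, threshold: float = 0.5
) -> tuple[bool, float]:
    """Tracking acceptance check: nuclear pixel overlap between time points.

    The overlap fraction is |A ∩ B| / min(|A|, |B|); the pair passes when
    the fraction reaches the threshold (default 0.5, i.e. at least 50%
    overlap). Masks must be congruent and nonempty.
    """
    a = np.asarray(mask_t).astype(bool)
    b = np.asarray(mask_t1).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise ValueError("masks must be nonempty")
    frac = float(np.logical_and(a, b).sum() / min(na, nb))
    return frac >= threshold, frac


def metrics_table(tracks: list[TrackMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "track_id": [m.track_id for m in tracks],
            "avg_speed_um_min": [m.avg_speed for m in tracks],
            "path_length_um": [m.path_length for m in tracks],
            "net_displacement_um": [m.net_displacement for m in tracks],
        }
    )


def group_summary(
    tracks: list[TrackMetrics], groups: dict[str, str]
) -> pd.DataFrame:
    """Per-group mean and sample s.d. (ddof=1) of each track metric.

    groups maps track_id to a group label; every metric row reports n, and
    single-track groups carry s.d. 0 with the n_eq_1 flag set (the spread
    of one observation is not estimable). Output is sorted by group so the
    table is independent of track order.
    """
    if not tracks:
        raise ValueError("no tracks given")
    missing = [m.track_id for m in tracks if m.track_id not in groups]
    if missing:
        raise ValueError(f"tracks without a group label: {missing}")
    df = metrics_table(tracks)
    df["group"] = df["track_id"].map(groups)
    rows = []
    for group, sub in sorted(df.groupby("group"), key=lambda kv: str(kv[0])):
        n = len(sub)
        for col in ("avg_speed_um_min", "path_length_um", "net_displacement_um"):
            rows.append(
                {
                    "group": group,
                    "metric": col,
                    "n": n,
                    "mean": sub[col].mean(),
                    "sd": 0.0 if n == 1 else sub[col].std(ddof=1),
                    "n_eq_1": n == 1,
                }
            )
    return pd.DataFrame(rows)


def read_tracks(path) -> list[Trajectory]:
    """Read trajectories from CSV columns track_id,t_min,x_um,y_um,z_um."""
    df = pd.read_csv(path)
    required = {"track_id", "t_min", "x_um", "y_um", "z_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"track CSV must have columns {sorted(required)}")
    out = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("t_min")
        out.append(
            Trajectory(
                str(tid),
                sub["t_min"].to_numpy(),
                sub[["x_um", "y_um", "z_um"]].to_numpy(),
            )
        )
    return out
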