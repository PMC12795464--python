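"""Shape dynamics: movement of cells through shape space along tracks.

Each tracked cell traces a trajectory in the (dc1, dc2) plane.  Step
vectors between consecutive frames quantify how fast and in which
direction the morphology changes: steps towards larger dc1 in the
high-dc1 (tailed-shape) region correspond to tail elongation, steps back
towards smaller dc1 to tail retraction.  Speeds are Euclidean distances
in shape space per frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

from shapespace.curves import DEFAULT_FRAME_INTERVAL
from shapespace.explore import RegionPartition

__all__ = [
    "ShapeTrajectory",
    "shape_speed",
    "direction_rose",
    "elongation_retraction_speeds",
    "compare_groups",
]


@dataclass
class ShapeTrajectory:
    """Per-track shape-space coordinates with step vectors."""

    track_id: str
    coords: np.ndarray  # (n_frames, >=2); only (dc1, dc2) enter dynamics
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def steps(self) -> np.ndarray:
        """Consecutive-frame displacement vectors in the (dc1, dc2) plane."""
        return np.diff(self.coords[:, :2], axis=0)


def shape_speed(traj: ShapeTrajectory) -> tuple[np.ndarray, float]:
    """Per-step shape-change speeds and their per-track mean.

    Speed is the Euclidean norm of the (dc1, dc2) step per frame interval.
    """
    if len(traj) < 2:
        raise ValueError("shape speed needs a track of at least 2 frames")
    speeds = np.hypot(traj.steps[:, 0], traj.steps[:, 1])
    return speeds, float(speeds.mean())


def direction_rose(
    trajs: Sequence[ShapeTrajectory],
    partition: RegionPartition | None = None,
    n_bins: int = 8,
) -> dict[int, dict]:
    """Angular histograms of step directions, per region of shape space.

    Each step is assigned to the region of its starting coordinate (all
    steps to region 0 if no partition is given).  Angles are
    ``atan2(d dc2, d dc1)`` binned into ``n_bins`` equal sectors starting
    at -pi.  Zero-length steps carry no direction; they are excluded from
    the histogram and counted separately.  Regions without any steps are
    flagged empty.
    """
    start_regions: dict[int, list[np.ndarray]] = {}
    offset = 0
    for traj in trajs:
        steps = traj.steps
        if partition is None:
            regions = np.zeros(len(steps), dtype=int)
        else:
            regions = partition.region_id[offset : offset + len(traj)][:-1]
            offset += len(traj)
        for reg, step in zip(regions, steps):
            start_regions.setdefault(int(reg), []).append(step)
    n_regions = partition.n_regions if partition is not None else 1
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    out: dict[int, dict] = {}
    for reg in range(n_regions):
        steps = np.array(start_regions.get(reg, [])).reshape(-1, 2)
        lengths = np.hypot(steps[:, 0], steps[:, 1]) if steps.size else np.array([])
        moving = steps[lengths > 0] if steps.size else steps
        angles = np.arctan2(moving[:, 1], moving[:, 0]) if moving.size else np.array([])
        hist, _ = np.histogram(angles, bins=edges)
        out[reg] = {
            "hist": hist,
            "bin_edges": edges,
            "n_steps": int(len(steps)),
            "n_zero_steps": int(len(steps) - len(moving)),
            "empty": len(steps) == 0,
        }
    return out


def _angle_deg(steps: np.ndarray) -> np.ndarray:
    return np.degrees(np.arctan2(steps[:, 1], steps[:, 0]))


def elongation_retraction_speeds(
    trajs: Sequence[ShapeTrajectory],
    region: tuple[float, float, float, float] | None = None,
) -> dict[str, np.ndarray]:
    """Split steps starting in a region into elongation and retraction events.

    ``region`` is ``(dc1_lo, dc1_hi, dc2_lo, dc2_hi)`` designating the
    tailed-shape territory (defaults to the upper half of the observed dc1
    range).  Steps with direction in [-45, 45) degrees (towards larger
    dc1) are elongation events; [135, 225) degrees are retraction events.
    Speeds are step norms per frame interval.
    """
    if not trajs:
        return {"elongation": np.array([]), "retraction": np.array([])}
    if region is None:
        all_coords = np.vstack([t.coords[:, :2] for t in trajs])
        lo1 = all_coords[:, 0].min() + 0.5 * np.ptp(all_coords[:, 0])
        region = (lo1, np.inf, -np.inf, np.inf)
    lo1, hi1, lo2, hi2 = region
    elong, retr = [], []
    for traj in trajs:
        xy = traj.coords[:, :2]
        steps = traj.steps
        start = xy[:-1]
        inside = (
            (start[:, 0] >= lo1)
            & (start[:, 0] < hi1)
            & (start[:, 1] >= lo2)
            & (start[:, 1] < hi2)
        )
        ang = _angle_deg(steps) % 360.0
        speed = np.hypot(steps[:, 0], steps[:, 1])
        is_elong = inside & ((ang < 45.0) | (ang >= 315.0)) & (speed > 0)
        is_retr = inside & (ang >= 135.0) & (ang < 225.0) & (speed > 0)
        elong.extend(speed[is_elong])
        retr.extend(speed[is_retr])
    return {"elongation": np.asarray(elong), "retraction": np.asarray(retr)}


def compare_groups(sample_a: np.ndarray, sample_b: np.ndarray) -> dict:
    """Kruskal-Wallis comparison of two speed samples, with summaries."""
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    small = a.size < 5 or b.size < 5
    if np.array_equal(a, b):
        stat, p = 0.0, 1.0
    else:
        stat, p = scipy.stats.kruskal(a, b)
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": int(a.size),
        "n_b": int(b.size),
        "small_sample_warning": small,
    }
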