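"""Contour containers, arc-length resampling, track assembly and I/O.

A cell outline enters the pipeline as an ordered list of planar points
(closure implicit: the first point is not repeated).  Before any distance
is computed the outline is converted to its canonical form: ``N`` complex
nodes, equally spaced in arc length along the polygon, translated so their
mean sits at the origin, and traversed counter-clockwise.  All downstream
modules operate on this :class:`NormalizedCurve` representation.

Tracks are per-cell sequences of frames.  Any gap in the frame sequence of
a cell splits the track into separate segments with derived IDs; segments
shorter than a minimum length are kept as a pool of still shapes so they
can still enter morphology-only analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Contour",
    "NormalizedCurve",
    "Track",
    "TrackSet",
    "resample_curve",
    "assemble_tracks",
    "read_contours",
    "write_contours",
    "contours_from_masks",
    "save_curves",
    "load_curves",
]

DEFAULT_NODES = 512
DEFAULT_FRAME_INTERVAL = 5.0  # minutes between frames


class DegenerateContourError(ValueError):
    """Raised for contours that cannot be resampled (too few points, zero perimeter)."""


@dataclass(frozen=True)
class Contour:
    """A closed planar outline of one cell in one frame.

    ``points`` is an ``(n, 2)`` float array of ordered boundary vertices;
    the curve is implicitly closed (last vertex connects back to the
    first).  Self-intersection is not checked.
    """

    points: np.ndarray
    cell_id: str = "0"
    frame: int = 0
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]  # drop explicit closure
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class NormalizedCurve:
    """Canonical curve: ``N`` complex nodes, zero mean, equal arc-length spacing."""

    nodes: np.ndarray
    source: tuple[str, int] = ("0", 0)

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=complex)
        if nodes.ndim != 1 or nodes.size < 8:
            raise ValueError("a normalized curve needs at least 8 complex nodes")
        object.__setattr__(self, "nodes", nodes)

    @property
    def N(self) -> int:
        return self.nodes.size

    @property
    def scale(self) -> float:
        """Root-mean-square node radius; the natural size unit of the curve."""
        return float(np.sqrt(np.mean(np.abs(self.nodes) ** 2)))

    def as_points(self) -> np.ndarray:
        return np.column_stack([self.nodes.real, self.nodes.imag])

    def validate(self, rtol_mean: float = 1e-9, rtol_spacing: float = 1e-6) -> None:
        """Check the canonical-form invariants; raise ``ValueError`` on failure."""
        scale = self.scale
        if scale == 0:
            raise ValueError("curve has zero extent")
        if abs(self.nodes.mean()) > rtol_mean * scale:
            raise ValueError("node mean is not at the origin")
        seg = np.abs(np.diff(np.concatenate([self.nodes, self.nodes[:1]])))
        # chord lengths approximate arc-length steps; allow curvature slack
        if seg.max() - seg.min() > max(rtol_spacing, 0.35) * seg.mean():
            raise ValueError("nodes are not (approximately) equally spaced")


@dataclass
class Track:
    """A gap-free per-cell sequence of frames with centroids and shapes."""

    cell_id: str
    frames: np.ndarray
    centroids: np.ndarray
    shapes: list[NormalizedCurve] = field(default_factory=list)
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.frames.size == 0:
            raise ValueError("a track needs at least one frame")
        if self.frames.size > 1 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("track frames must be contiguous and increasing")

    def __len__(self) -> int:
        return int(self.frames.size)


@dataclass
class TrackSet:
    """Result of track assembly: usable tracks plus a still-image shape pool."""

    tracks: list[Track]
    stills: list[Contour]


def _force_ccw(points: np.ndarray) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area < 0:
        # reverse traversal but keep the first vertex first
        points = np.vstack([points[:1], points[1:][::-1]])
    return points


def resample_curve(c: Contour, N: int = DEFAULT_NODES) -> NormalizedCurve:
    """Resample a contour to ``N`` nodes equally spaced in arc length.

    The polygon is forced counter-clockwise, node 0 is placed at the input's
    first vertex, nodes are linearly interpolated along the polygon at equal
    arc-length steps, and the result is translated to zero mean.

    Parameters
    ----------
    c : Contour
        Input outline with at least 3 points and positive perimeter.
    N : int
        Node count, at least 8.  512 nodes resolve typical cell outlines.
    """
    if N < 8:
        raise ValueError(f"N must be >= 8, got {N}")
    if c.n_points < 3:
        raise DegenerateContourError(
            f"contour ({c.cell_id}, {c.frame}) has {c.n_points} points; need >= 3"
        )
    pts = _force_ccw(np.asarray(c.points, dtype=float))
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = cum[-1]
    if perimeter <= 0:
        raise DegenerateContourError(
            f"contour ({c.cell_id}, {c.frame}) has zero perimeter"
        )
    targets = np.arange(N) * (perimeter / N)
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    nodes = x + 1j * y
    # Equal steps along the SOURCE polygon do not give exactly equal chords
    # on the output polygon (chords shorten where curvature concentrates).
    # Iterate the re-chording to its fixed point so the node spacing is
    # self-consistent and resampling is idempotent.
    scale = float(np.sqrt(np.mean(np.abs(nodes - nodes.mean()) ** 2))) or 1.0
    for _ in range(50):
        prev = nodes
        ring = np.concatenate([nodes, nodes[:1]])
        seg = np.abs(np.diff(ring))
        cum_i = np.concatenate([[0.0], np.cumsum(seg)])
        t = np.arange(N) * (cum_i[-1] / N)
        nodes = np.interp(t, cum_i, ring.real) + 1j * np.interp(t, cum_i, ring.imag)
        if np.max(np.abs(nodes - prev)) < 1e-10 * scale:
            break
    nodes = nodes - nodes.mean()
    return NormalizedCurve(nodes=nodes, source=(str(c.cell_id), int(c.frame)))


def assemble_tracks(
    contours: Iterable[Contour],
    min_frames: int = 5,
    N: int = DEFAULT_NODES,
    resample: bool = True,
) -> TrackSet:
    """Group contours into gap-free per-cell tracks.

    Frame gaps within one cell ID split the sequence into separate tracks
    with derived IDs (``"<cell_id>.0"``, ``"<cell_id>.1"``, ...).  Segments
    shorter than ``min_frames`` are returned in the still-shape pool rather
    than as tracks, so their morphology can still be analysed.

    Raises on duplicate ``(cell_id, frame)`` pairs.
    """
    by_cell: dict[str, list[Contour]] = {}
    seen: set[tuple[str, int]] = set()
    for c in contours:
        key = (str(c.cell_id), int(c.frame))
        if key in seen:
            raise ValueError(f"duplicate (cell_id, frame) pair {key}")
        seen.add(key)
        by_cell.setdefault(str(c.cell_id), []).append(c)

    tracks: list[Track] = []
    stills: list[Contour] = []
    for cell_id in sorted(by_cell):
        cs = sorted(by_cell[cell_id], key=lambda c: c.frame)
        segments: list[list[Contour]] = [[cs[0]]]
        for c in cs[1:]:
            if c.frame == segments[-1][-1].frame + 1:
                segments[-1].append(c)
            else:
                segments.append([c])
        multi = len(segments) > 1
        for i, seg in enumerate(segments):
            if len(seg) < min_frames:
                stills.extend(seg)
                continue
            tid = f"{cell_id}.{i}" if multi else cell_id
            shapes = [resample_curve(c, N) for c in seg] if resample else []
            tracks.append(
                Track(
                    cell_id=tid,
                    frames=np.array([c.frame for c in seg]),
                    centroids=np.array([c.centroid() for c in seg]),
                    shapes=shapes,
                    frame_interval=seg[0].frame_interval,
                )
            )
    return TrackSet(tracks=tracks, stills=stills)


# ---------------------------------------------------------------------------
# I/O


def write_contours(path: str | Path, contours: Sequence[Contour], format: str | None = None) -> None:
    """Write contours as delimited text (``csv``) or structured text (``json``)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        frames = [
            pd.DataFrame(
                {
                    "cell_id": c.cell_id,
                    "frame": c.frame,
                    "x": c.points[:, 0],
                    "y": c.points[:, 1],
                }
            )
            for c in contours
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    elif fmt == "json":
        payload = [
            {"cell_id": c.cell_id, "frame": int(c.frame), "points": c.points.tolist()}
            for c in contours
        ]
        path.write_text(json.dumps(payload))
    else:
        raise ValueError(f"unknown contour format {fmt!r} (use 'csv' or 'json')")


def read_contours(
    path: str | Path,
    format: str | None = None,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> list[Contour]:
    """Read contours from delimited text, structured text, or a mask stack.

    ``csv``: one row per boundary point with columns cell_id, frame, x, y.
    ``json``: list of ``{cell_id, frame, points: [[x, y], ...]}`` records.
    ``tif``/``tiff``: multi-page label-mask stack, boundaries traced per label.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path)
        missing = {"cell_id", "frame", "x", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"contour file {path} is missing columns: {sorted(missing)}")
        out = []
        for (cell_id, frame), g in df.groupby(["cell_id", "frame"], sort=True):
            out.append(
                Contour(
                    points=g[["x", "y"]].to_numpy(float),
                    cell_id=str(cell_id),
                    frame=int(frame),
                    frame_interval=frame_interval,
                )
            )
        return out
    if fmt == "json":
        payload = json.loads(path.read_text())
        return [
            Contour(
                points=np.asarray(rec["points"], dtype=float),
                cell_id=str(rec["cell_id"]),
                frame=int(rec["frame"]),
                frame_interval=frame_interval,
            )
            for rec in payload
        ]
    if fmt in {"tif", "tiff"}:
        import tifffile

        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        return contours_from_masks(stack, frame_interval=frame_interval)
    raise ValueError(f"unknown contour format {fmt!r} (use 'csv', 'json' or 'tiff')")


def save_curves(path: str | Path, curves: Sequence[NormalizedCurve]) -> None:
    """Persist normalized curves (complex node arrays + index) to HDF5."""
    import h5py

    nodes = np.stack([c.nodes for c in curves])
    with h5py.File(path, "w") as f:
        f.create_dataset("nodes", data=nodes)
        f.create_dataset(
            "cell_id", data=np.array([c.source[0] for c in curves], dtype="S")
        )
        f.create_dataset("frame", data=np.array([c.source[1] for c in curves]))


def load_curves(path: str | Path) -> list[NormalizedCurve]:
    import h5py

    with h5py.File(path, "r") as f:
        nodes = f["nodes"][...]
        ids = [s.decode() for s in f["cell_id"][...]]
        frames = [int(x) for x in f["frame"][...]]
    return [
        NormalizedCurve(nodes=nodes[i], source=(ids[i], frames[i]))
        for i in range(nodes.shape[0])
    ]


def contours_from_masks(
    stack: np.ndarray, frame_interval: float = DEFAULT_FRAME_INTERVAL
) -> list[Contour]:
    """Trace outer cell boundaries from a stack of label masks.

    For each frame and label the largest connected component is traced with
    a sub-pixel 0.5-level contour (marching squares) on a lightly smoothed
    indicator field — the smoothing removes the pixel staircase so traced
    perimeters approximate the true boundary length.  The longest closed
    boundary is kept as the outer one.
    """
    from scipy.ndimage import gaussian_filter
    from skimage import measure

    out: list[Contour] = []
    for frame, mask in enumerate(np.asarray(stack)):
        for label in np.unique(mask):
            if label == 0:
                continue
            binary = (mask == label).astype(float)
            padded = gaussian_filter(np.pad(binary, 2), sigma=1.0)
            traces = measure.find_contours(padded, 0.5)
            if not traces:
                continue
            boundary = max(traces, key=len)
            # find_contours yields (row, col); convert to (x, y), unpad
            pts = np.column_stack([boundary[:, 1] - 2.0, boundary[:, 0] - 2.0])
            out.append(
                Contour(
                    points=pts,
                    cell_id=str(int(label)),
                    frame=frame,
                    frame_interval=frame_interval,
                )
            )
    return out
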