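"""Shape features and shape-space exploration tools.

Classical geometric descriptors are computed for every shape so that the
abstract diffusion coordinates can be interpreted: which feature does
each axis capture?  The space can then be partitioned — by equal-width
grid slicing on the first two coordinates, by a self-organising map, or
by affinity-propagation clustering of the raw BAM distances followed by
hierarchical grouping of the exemplars — and the occupancy of regions
compared between experimental groups (e.g. control versus perturbation).

Feature conventions: circularity is ``perimeter^2 / (4 pi area)`` (1 for
a circle, growing with elongation and boundary complexity); eccentricity
is the standard ellipse eccentricity ``sqrt(1 - (b/a)^2)`` of the
second-moment ellipse; extent is the area fraction of the bounding box
aligned with the principal axes (so it is rotation invariant, unlike an
image-axis-aligned box); symmetry is one minus the scale-normalised BAM
distance of the curve to its mirror image; irregularity is the max/mean
centre-distance ratio; irregularity2 is the perimeter-normalised total
absolute deviation of the turning angle from a circle's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.cluster import AffinityPropagation

from shapespace.bam import (
    CurveCache,
    DissimilarityMatrix,
    apply_alignment,
    bam_fast,
    pairwise_matrix,
)
from shapespace.curves import Contour, NormalizedCurve, resample_curve
from shapespace.embedding import ShapeSpace

__all__ = [
    "FEATURE_NAMES",
    "RegionPartition",
    "ClusterResult",
    "compute_features",
    "feature_table",
    "feature_correlations",
    "slice_space",
    "average_shape",
    "cluster_shapes",
    "som_zones",
    "group_fractions",
]

FEATURE_NAMES = [
    "area",
    "perimeter",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "orientation",
    "convex_area",
    "solidity",
    "extent",
    "circularity",
    "symmetry",
    "max_centre_distance",
    "min_centre_distance",
    "minmax_ratio",
    "irregularity",
    "irregularity2",
]


def _polygon_moments(pts: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Area, centroid and area-normalised second central moments of a polygon."""
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if area == 0:
        raise ValueError("degenerate polygon with zero area")
    cx = np.sum((x + x1) * cross) / (6 * area)
    cy = np.sum((y + y1) * cross) / (6 * area)
    # second moments about the origin, then shifted to the centroid
    sxx = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12
    syy = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12
    sxy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24
    mxx = sxx / area - cx**2
    myy = syy / area - cy**2
    mxy = sxy / area - cx * cy
    return float(area), np.array([cx, cy]), np.array([[mxx, mxy], [mxy, myy]])


def compute_features(
    curve: NormalizedCurve | Contour,
    cache: CurveCache | None = None,
) -> dict[str, float]:
    """Geometric shape descriptors of one closed curve.

    A :class:`Contour` input is first resampled to the canonical form;
    its original vertices (which carry no resampling error) are kept for
    the centre-distance features.  Ellipse quantities come from the
    second-moment (best-fit) ellipse of the polygon; solidity from the
    convex hull; centre distances from the boundary centroid.
    """
    radii = None
    if isinstance(curve, Contour):
        orig = curve.points - curve.points.mean(axis=0)
        radii = np.hypot(orig[:, 0], orig[:, 1])
        curve = resample_curve(curve, max(256, min(512, curve.n_points * 4)))
    pts = curve.as_points()
    area, _centroid, cov = _polygon_moments(pts)
    if area < 0:  # clockwise polygon; features are orientation-independent
        area = -area
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    perimeter = float(np.hypot(d[:, 0], d[:, 1]).sum())

    evals, _ = np.linalg.eigh(cov)
    lam_minor, lam_major = float(max(evals[0], 0.0)), float(max(evals[1], 0.0))
    major = 4.0 * np.sqrt(lam_major)
    minor = 4.0 * np.sqrt(lam_minor)
    eccentricity = float(np.sqrt(max(0.0, 1.0 - lam_minor / max(lam_major, 1e-300))))
    orientation = float(0.5 * np.arctan2(2 * cov[0, 1], cov[0, 0] - cov[1, 1]))

    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    convex_area = float(hull.volume)
    solidity = area / convex_area

    # bounding box in the principal-axes frame (rotation invariant)
    c, s = np.cos(orientation), np.sin(orientation)
    aligned = pts @ np.array([[c, s], [-s, c]]).T
    bbox_area = float(np.ptp(aligned[:, 0]) * np.ptp(aligned[:, 1]))
    extent = area / bbox_area
    circularity = perimeter**2 / (4 * np.pi * area)

    if radii is None:
        radii = np.abs(curve.nodes)  # node mean is the origin
    max_cd, min_cd = float(radii.max()), float(radii.min())

    mirror = NormalizedCurve(np.conj(curve.nodes)[::-1], source=curve.source)
    d_mirror = bam_fast(curve, mirror, cache).distance
    symmetry = 1.0 - d_mirror / (2.0 * curve.scale)

    # turning angles of the polygon; a circle turns 2 pi / N at every node
    edges = np.diff(np.concatenate([curve.nodes, curve.nodes[:2]]))
    turn = np.angle(edges[1:] / edges[:-1])
    irregularity2 = float(np.sum(np.abs(turn - 2 * np.pi / curve.N)) / (2 * np.pi))

    return {
        "area": float(area),
        "perimeter": perimeter,
        "major_axis_length": major,
        "minor_axis_length": minor,
        "eccentricity": eccentricity,
        "orientation": orientation,
        "convex_area": convex_area,
        "solidity": float(solidity),
        "extent": float(extent),
        "circularity": float(circularity),
        "symmetry": float(symmetry),
        "max_centre_distance": max_cd,
        "min_centre_distance": min_cd,
        "minmax_ratio": min_cd / max_cd,
        "irregularity": float(max_cd / radii.mean()),
        "irregularity2": irregularity2,
    }


def feature_table(
    curves: Sequence[NormalizedCurve], cache: CurveCache | None = None
) -> pd.DataFrame:
    """Feature records for a collection of curves, indexed like the curves."""
    cache = cache or CurveCache()
    rows = [compute_features(c, cache) for c in curves]
    df = pd.DataFrame(rows)
    df.index = pd.MultiIndex.from_tuples(
        [c.source for c in curves], names=["cell_id", "frame"]
    )
    return df


def feature_correlations(space: ShapeSpace, features: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every shape feature with every diffusion coordinate.

    Zero-variance features yield NaN (undefined), not zero.
    """
    if len(features) != space.M:
        raise ValueError("feature table and embedding have different sizes")
    out = np.full((features.shape[1], space.k), np.nan)
    X = space.coords - space.coords.mean(axis=0)
    xs = np.sqrt((X**2).sum(axis=0))
    for j, name in enumerate(features.columns):
        y = features[name].to_numpy(float)
        y = y - y.mean()
        ys = np.sqrt((y**2).sum())
        if ys == 0:
            continue
        out[j] = (X.T @ y) / (xs * ys)
    return pd.DataFrame(
        out,
        index=features.columns,
        columns=[f"dc{i + 1}" for i in range(space.k)],
    )


@dataclass
class RegionPartition:
    """Assignment of every embedded shape to a region of shape space."""

    kind: str  # grid | som | manual
    region_id: np.ndarray  # int per shape; -1 marks unassigned
    n_regions: int
    meta: dict = field(default_factory=dict)

    def counts(self) -> np.ndarray:
        assigned = self.region_id[self.region_id >= 0]
        return np.bincount(assigned, minlength=self.n_regions)

    def empty_regions(self) -> np.ndarray:
        return np.flatnonzero(self.counts() == 0)


def slice_space(space: ShapeSpace, n1: int, n2: int) -> RegionPartition:
    """Partition shape space by an ``n1 x n2`` equal-width grid on (dc1, dc2).

    Slice intervals are half-open ``[lo, hi)`` with the topmost slice
    closed, so boundary points are never double-counted.  Region IDs run
    row-major: ``id = i1 * n2 + i2``.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("grid sizes must be >= 1")
    xy = space.coords[:, :2]
    ids = np.zeros(space.M, dtype=int)
    strides = (n2, 1)
    for axis, n in ((0, n1), (1, n2)):
        lo, hi = xy[:, axis].min(), xy[:, axis].max()
        width = (hi - lo) / n if hi > lo else 1.0
        bins = np.minimum((np.floor((xy[:, axis] - lo) / width)).astype(int), n - 1)
        ids += bins * strides[axis]
    bounds = {
        "dc1_edges": np.linspace(xy[:, 0].min(), xy[:, 0].max(), n1 + 1),
        "dc2_edges": np.linspace(xy[:, 1].min(), xy[:, 1].max(), n2 + 1),
    }
    return RegionPartition(
        kind="grid", region_id=ids, n_regions=n1 * n2, meta={"shape": (n1, n2), **bounds}
    )


def average_shape(
    curves: Sequence[NormalizedCurve], cache: CurveCache | None = None
) -> NormalizedCurve:
    """BAM-aligned node-wise mean shape of a set of curves.

    All curves are aligned (optimal cyclic shift and rotation) to the set
    medoid — the member with the smallest summed BAM distance to the rest —
    then averaged node by node and re-centred.  Deterministic: ties on the
    medoid go to the earliest curve.
    """
    if len(curves) == 0:
        raise ValueError("average_shape needs at least one curve")
    if len(curves) == 1:
        return curves[0]
    cache = cache or CurveCache()
    D = pairwise_matrix(curves).values
    medoid = int(np.argmin(D.sum(axis=1)))
    ref = curves[medoid]
    acc = np.zeros(ref.N, dtype=complex)
    for c in curves:
        res = bam_fast(ref, c, cache)
        acc += apply_alignment(c.nodes, res.shift, res.rotation)
    mean_nodes = acc / len(curves)
    mean_nodes = mean_nodes - mean_nodes.mean()
    return NormalizedCurve(mean_nodes, source=("average", 0))


@dataclass
class ClusterResult:
    """Affinity-propagation exemplars with a hierarchical grouping on top."""

    exemplar_indices: np.ndarray  # indices into the curve set
    labels: np.ndarray  # AP cluster per shape
    higher_labels: np.ndarray  # hierarchical group per shape (0..n_higher-1)
    seriation_order: np.ndarray  # display order of exemplars (dendrogram leaves)
    converged: bool
    n_iter: int


def cluster_shapes(
    D: DissimilarityMatrix,
    n_higher: int = 4,
    damping: float = 0.9,
    max_iter: int = 1000,
    preference: float | None = None,
) -> ClusterResult:
    """Exemplar clustering of the raw distances, independent of the embedding.

    Affinity propagation runs on negated squared distances (preference:
    the median similarity unless given).  The exemplars are then grouped
    by average-linkage hierarchical clustering cut at ``n_higher`` groups;
    the dendrogram leaf order serves as a seriation for display.
    """
    S = -(D.values**2)
    if preference is None:
        preference = float(np.median(S))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ap = AffinityPropagation(
            affinity="precomputed",
            damping=damping,
            max_iter=max_iter,
            preference=preference,
            random_state=0,
        ).fit(S)
    converged = not any("did not converge" in str(w.message) for w in caught)
    exemplars = np.asarray(ap.cluster_centers_indices_)
    labels = np.asarray(ap.labels_)
    if exemplars is None or exemplars.size == 0 or np.any(labels < 0):
        raise RuntimeError(
            f"affinity propagation did not converge after {ap.n_iter_} iterations "
            f"(damping={damping}, preference={preference})"
        )
    n_ex = exemplars.size
    if n_ex == 1:
        return ClusterResult(
            exemplar_indices=exemplars,
            labels=labels,
            higher_labels=np.zeros_like(labels),
            seriation_order=np.array([0]),
            converged=converged,
            n_iter=int(ap.n_iter_),
        )
    sub = D.values[np.ix_(exemplars, exemplars)]
    iu = np.triu_indices(n_ex, k=1)
    Z = sch.linkage(sub[iu], method="average")
    cut = sch.fcluster(Z, t=min(n_higher, n_ex), criterion="maxclust") - 1
    order = np.asarray(sch.leaves_list(Z))
    return ClusterResult(
        exemplar_indices=exemplars,
        labels=labels,
        higher_labels=cut[labels],
        seriation_order=order,
        converged=converged,
        n_iter=int(ap.n_iter_),
    )


def som_zones(
    space: ShapeSpace,
    grid: tuple[int, int] = (2, 2),
    seed: int = 0,
    n_epochs: int = 40,
) -> RegionPartition:
    """Partition shape space with a self-organising map on (dc1, dc2).

    A small rectangular SOM is trained online with an exponentially
    decaying learning rate and neighbourhood radius; the zones are the
    Voronoi cells of the final node prototypes.  Fully deterministic for
    a given seed.
    """
    rows, cols = grid
    if rows * cols < 2:
        raise ValueError("SOM grid needs at least 2 nodes")
    X = space.coords[:, :2]
    rng = np.random.default_rng(seed)
    # initialise prototypes on a regular grid spanning the data
    gx = np.linspace(X[:, 0].min(), X[:, 0].max(), rows + 2)[1:-1]
    gy = np.linspace(X[:, 1].min(), X[:, 1].max(), cols + 2)[1:-1]
    proto = np.array([[x, y] for x in gx for y in gy], dtype=float)
    grid_pos = np.array([[i, j] for i in range(rows) for j in range(cols)], dtype=float)

    n = X.shape[0]
    total = n_epochs * n
    lr0, lr1 = 0.5, 0.01
    r0, r1 = max(rows, cols) / 2.0, 0.5
    t = 0
    for _ in range(n_epochs):
        for idx in rng.permutation(n):
            frac = t / max(total - 1, 1)
            lr = lr0 * (lr1 / lr0) ** frac
            radius = r0 * (r1 / r0) ** frac
            x = X[idx]
            bmu = int(np.argmin(((proto - x) ** 2).sum(axis=1)))
            g2 = ((grid_pos - grid_pos[bmu]) ** 2).sum(axis=1)
            h = np.exp(-g2 / (2 * radius**2))
            proto += lr * h[:, None] * (x - proto)
            t += 1
    assign = np.argmin(
        ((X[:, None, :] - proto[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    return RegionPartition(
        kind="som",
        region_id=assign.astype(int),
        n_regions=rows * cols,
        meta={"shape": grid, "prototypes": proto, "seed": seed},
    )


def group_fractions(
    partition: RegionPartition, groups: Sequence | np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group fractions (and counts) of shapes across regions.

    Returns ``(fractions, counts)`` with one row per group and one column
    per region; each fraction row sums to 1.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != partition.region_id.shape[0]:
        raise ValueError("every shape needs a group label")
    if pd.isna(groups).any():
        raise ValueError("group labels must not contain missing values")
    names = sorted(set(groups.tolist()))
    counts = np.zeros((len(names), partition.n_regions), dtype=int)
    for gi, g in enumerate(names):
        sel = partition.region_id[groups == g]
        sel = sel[sel >= 0]
        counts[gi] = np.bincount(sel, minlength=partition.n_regions)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("a group has no assigned shapes")
    cols = [f"region_{i}" for i in range(partition.n_regions)]
    counts_df = pd.DataFrame(counts, index=names, columns=cols)
    frac_df = pd.DataFrame(counts / totals, index=names, columns=cols)
    return frac_df, counts_df
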