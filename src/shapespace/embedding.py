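"""Diffusion-map shape space and out-of-sample extension.

The BAM dissimilarity matrix is converted to affinities with a Gaussian
kernel, ``w(u, v) = exp(-d(u, v)^2 / (2 sigma^2))``, with the bandwidth
``sigma`` set by default to the median of all pairwise distances — a
robust choice of contextual scale.  Row-normalising the affinity matrix
gives a Markov operator whose leading eigenvectors are the diffusion
coordinates; the trivial constant eigenvector (eigenvalue 1) is dropped
and each remaining eigenvector is scaled by its eigenvalue (diffusion
time t = 1).  Five coordinates suffice for typical cell-shape data; the
first two usually carry most of the variation (elongation and
irregularity for migrating epithelial cells).

New shapes are placed into an existing space without changing its
geometry, either by averaging the coordinates of the K nearest training
shapes (by BAM distance) or by a multiscale Laplacian-pyramid kernel
regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from shapespace.bam import CurveCache, DissimilarityMatrix, bam_fast
from shapespace.curves import NormalizedCurve

__all__ = [
    "ShapeSpace",
    "median_bandwidth",
    "gaussian_kernel",
    "embed",
    "embed_distances",
    "variance_captured",
    "oose_knn",
    "oose_laplacian_pyramid",
    "OoseResult",
]


@dataclass
class ShapeSpace:
    """Diffusion-map embedding: coordinates, spectrum and kernel bandwidth.

    ``coords`` is M x k with row order matching ``curve_index``;
    ``eigenvalues`` holds the k+1 leading eigenvalues of the Markov
    operator in descending order, the first of which is the trivial 1.
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    sigma: float
    curve_index: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if not self.curve_index:
            self.curve_index = [(str(i), 0) for i in range(self.coords.shape[0])]
        if len(self.curve_index) != self.coords.shape[0]:
            raise ValueError("curve_index length must match number of rows")

    @property
    def M(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def coords_for(self, key: tuple[str, int]) -> np.ndarray:
        return self.coords[self.curve_index.index(key)]

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("coords", data=self.coords)
            f.create_dataset("eigenvalues", data=self.eigenvalues)
            f.attrs["sigma"] = self.sigma
            f.create_dataset(
                "cell_id", data=np.array([c for c, _ in self.curve_index], dtype="S")
            )
            f.create_dataset("frame", data=np.array([fr for _, fr in self.curve_index]))

    @classmethod
    def load(cls, path: str | Path) -> "ShapeSpace":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                coords=f["coords"][...],
                eigenvalues=f["eigenvalues"][...],
                sigma=float(f.attrs["sigma"]),
                curve_index=list(
                    zip(
                        [s.decode() for s in f["cell_id"][...]],
                        [int(x) for x in f["frame"][...]],
                    )
                ),
            )


def median_bandwidth(D: DissimilarityMatrix) -> float:
    """Median of the off-diagonal pairwise distances."""
    sigma = float(np.median(D.offdiag()))
    if sigma <= 0:
        raise ValueError("median pairwise distance is zero; cannot set bandwidth")
    return sigma


def gaussian_kernel(
    D: DissimilarityMatrix, sigma: float | Literal["median"] = "median"
) -> tuple[np.ndarray, float]:
    """Gaussian affinities ``exp(-d^2 / (2 sigma^2))``; returns (W, sigma)."""
    if sigma == "median":
        sigma = median_bandwidth(D)
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    W = np.exp(-(D.values**2) / (2.0 * sigma**2))
    return W, sigma


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each eigenvector positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def embed(
    W: np.ndarray,
    sigma: float,
    k: int = 5,
    alpha: float = 0.0,
    sparse: bool = False,
    curve_index: list[tuple[str, int]] | None = None,
    seed: int = 0,
) -> ShapeSpace:
    """Diffusion-map embedding of a symmetric affinity matrix.

    The operator is the row-normalised kernel (optionally density-corrected
    with exponent ``alpha`` in {0, 1/2, 1}); its top ``k + 1`` eigenpairs
    are found via the symmetric conjugate, the trivial constant eigenvector
    is dropped, and coordinate ``i`` is ``lambda_i * psi_i``.  With
    ``sparse=True`` affinities below 1e-12 are dropped and an iterative
    eigensolver with a seeded start vector is used.
    """
    W = np.asarray(W, dtype=float)
    M = W.shape[0]
    if W.shape != (M, M):
        raise ValueError("affinity matrix must be square")
    if k + 1 > M:
        raise ValueError(f"k + 1 = {k + 1} exceeds number of samples {M}")
    if alpha not in (0.0, 0.5, 1.0):
        raise ValueError("alpha must be one of 0, 0.5, 1")
    if alpha > 0:
        q = W.sum(axis=1)
        W = W / np.outer(q**alpha, q**alpha)
    d = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    # symmetric conjugate of the Markov operator: same spectrum, real eigenvectors
    S = W * np.outer(inv_sqrt, inv_sqrt)
    if sparse:
        Ssp = scipy.sparse.csr_matrix(np.where(S >= 1e-12, S, 0.0))
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(M)
        vals, vecs = scipy.sparse.linalg.eigsh(Ssp, k=k + 1, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    else:
        vals, vecs = scipy.linalg.eigh(S, subset_by_index=(M - k - 1, M - 1))
        vals, vecs = vals[::-1], vecs[:, ::-1]
    # back to eigenvectors of the Markov operator
    psi = vecs * inv_sqrt[:, None]
    # normalise so the trivial eigenvector is the constant 1 vector
    psi = psi / np.linalg.norm(psi, axis=0) * np.sqrt(M)
    psi = _fix_signs(psi)
    coords = psi[:, 1:] * vals[1:][None, :]
    return ShapeSpace(
        coords=coords,
        eigenvalues=vals,
        sigma=float(sigma),
        curve_index=curve_index or [],
    )


def embed_distances(
    D: DissimilarityMatrix,
    k: int = 5,
    sigma: float | Literal["median"] = "median",
    **kwargs,
) -> ShapeSpace:
    """Convenience: Gaussian kernel + diffusion map straight from distances."""
    W, sig = gaussian_kernel(D, sigma)
    return embed(W, sig, k=k, curve_index=list(D.curve_index), **kwargs)


def variance_captured(space: ShapeSpace, dims: int) -> float:
    """Fraction of diffusion-distance energy in the leading ``dims`` coordinates.

    Defined as the sum of squared non-trivial eigenvalues up to ``dims``
    over the total across all ``k`` retained coordinates.
    """
    if dims < 0 or dims > space.k:
        raise ValueError(f"dims must be in [0, {space.k}]")
    lam2 = space.eigenvalues[1:] ** 2
    return float(lam2[:dims].sum() / lam2.sum())


def _query_distances(
    training_curves: Sequence[NormalizedCurve],
    query: NormalizedCurve,
    cache: CurveCache | None = None,
) -> np.ndarray:
    cache = cache or CurveCache()
    return np.array([bam_fast(query, c, cache).distance for c in training_curves])


def oose_knn(
    space: ShapeSpace,
    training_curves: Sequence[NormalizedCurve],
    query: NormalizedCurve,
    K: int = 5,
    cache: CurveCache | None = None,
) -> np.ndarray:
    """K-nearest-neighbour out-of-sample extension.

    The query's coordinates are the unweighted mean of the diffusion
    coordinates of its K nearest training shapes by BAM distance.  The
    learned geometry is untouched.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > space.M:
        raise ValueError(f"K = {K} exceeds training size {space.M}")
    if len(training_curves) != space.M:
        raise ValueError("training curve count must match the embedding")
    dists = _query_distances(training_curves, query, cache)
    nearest = np.argsort(dists, kind="stable")[:K]
    return space.coords[nearest].mean(axis=0)


@dataclass(frozen=True)
class OoseResult:
    """Coordinates from an extension plus a confidence flag."""

    coords: np.ndarray
    low_confidence: bool


def oose_laplacian_pyramid(
    space: ShapeSpace,
    training_curves: Sequence[NormalizedCurve],
    query: NormalizedCurve,
    max_levels: int = 12,
    cache: CurveCache | None = None,
    training_distances: np.ndarray | None = None,
) -> OoseResult:
    """Laplacian-pyramid out-of-sample extension.

    Multiscale kernel regression: level ``l`` fits the residual of the
    previous levels with a Gaussian kernel of bandwidth ``sigma / 2^l``,
    stopping when the training residual stops decreasing.  Queries whose
    minimum BAM distance to the training set exceeds ten bandwidths are
    flagged as low-confidence extrapolations.
    """
    if len(training_curves) != space.M:
        raise ValueError("training curve count must match the embedding")
    cache = cache or CurveCache()
    n = space.M
    if training_distances is None:
        Dtr = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                Dtr[i, j] = Dtr[j, i] = bam_fast(
                    training_curves[i], training_curves[j], cache
                ).distance
    else:
        Dtr = np.asarray(training_distances, dtype=float)
    dq = _query_distances(training_curves, query, cache)

    residual = space.coords.copy()
    pred_query = np.zeros(space.k)
    best_norm = np.inf
    for level in range(max_levels):
        s = space.sigma / (2.0**level)
        Ktr = np.exp(-(Dtr**2) / (2 * s**2))
        kq = np.exp(-(dq**2) / (2 * s**2))
        qden = kq.sum()
        if qden <= 0:
            break
        level_train = (Ktr @ residual) / Ktr.sum(axis=1, keepdims=True)
        level_query = (kq @ residual) / qden
        new_residual = residual - level_train
        norm = float(np.linalg.norm(new_residual))
        if norm >= best_norm:
            break
        best_norm = norm
        pred_query = pred_query + level_query
        residual = new_residual
    low_conf = bool(dq.min() > 10.0 * space.sigma)
    return OoseResult(coords=pred_query, low_confidence=low_conf)
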