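"""Best Alignment Metric (BAM) between closed planar curves.

BAM measures the residual L2 difference between two closed curves after
the best rigid alignment: translation (removed once and for all by
centering each curve at the origin), rotation of the plane, and cyclic
renumbering of the nodes.  For curves ``u, v`` of ``N`` zero-mean complex
nodes,

    d(u, v)^2 = (1/N) * min_{r, theta} sum_j | u_j - e^{i theta} v_{j+r} |^2

with the index ``j + r`` taken modulo ``N``.  For a fixed shift ``r`` the
optimal rotation is analytic: expanding the square gives

    sum_j |u_j|^2 + sum_j |v_j|^2 - 2 Re( e^{-i theta} C(r) ),
    C(r) = sum_j u_j * conj(v_{j+r}),

which is minimised by ``theta = arg C(r)``, leaving ``-2 |C(r)|``.  The
whole shift search therefore reduces to the modulus of the circular
cross-correlation of the two node sequences, computable for all ``N``
shifts at once with a forward/inverse FFT pair.  Per-curve transforms are
cached so that building an M x M dissimilarity matrix costs one FFT pair
per curve plus one inverse FFT per pair of curves.

Reflection is deliberately NOT a permissible transformation by default:
mirror-image shapes (e.g. left- versus right-turning cells) stay distinct.
An optional reflection mode compares against the conjugated, reversed
curve as well and keeps the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from shapespace.curves import NormalizedCurve

__all__ = [
    "AlignmentResult",
    "CurveCache",
    "DissimilarityMatrix",
    "bam_brute_force",
    "bam_fast",
    "pairwise_matrix",
    "apply_alignment",
]

_NEG_TOL = 1e-9  # relative tolerance for clamping tiny negative raw distances


@dataclass(frozen=True)
class AlignmentResult:
    """Distance plus the transform of the second curve that attains it.

    Applying ``e^{i rotation} * roll(v, -shift)`` to the second curve's
    nodes aligns it onto the first at the reported distance.
    """

    distance: float
    shift: int
    rotation: float
    raw: float  # N * distance^2, the quantity the fast algorithm works with

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", float(self.rotation) % (2 * np.pi))


def apply_alignment(nodes: np.ndarray, shift: int, rotation: float) -> np.ndarray:
    """Return ``e^{i rotation} * v_{j+shift}`` — the aligned copy of a curve."""
    return np.exp(1j * rotation) * np.roll(nodes, -shift)


def _check_pair(u: NormalizedCurve, v: NormalizedCurve) -> None:
    if u.N != v.N:
        raise ValueError(f"node counts differ: {u.N} != {v.N}")


def _result_from_correlation(corr: np.ndarray, s_u: float, s_v: float, N: int) -> AlignmentResult:
    mod = np.abs(corr)
    r = int(np.argmax(mod))  # first (smallest) shift wins ties
    A = float(mod[r])
    raw = s_u + s_v - 2.0 * A
    if raw < -_NEG_TOL * max(s_u + s_v, 1.0):
        raise FloatingPointError(
            f"negative squared distance {raw}; transform inputs are inconsistent"
        )
    raw = max(raw, 0.0)
    return AlignmentResult(
        distance=float(np.sqrt(raw / N)),
        shift=r,
        rotation=float(np.angle(corr[r])),
        raw=raw,
    )


def bam_brute_force(u: NormalizedCurve, v: NormalizedCurve) -> AlignmentResult:
    """Reference BAM: explicit loop over all cyclic shifts.

    O(N^2); kept as the independent oracle for the FFT formulation.
    """
    _check_pair(u, v)
    N = u.N
    corr = np.empty(N, dtype=complex)
    for r in range(N):
        corr[r] = np.sum(u.nodes * np.conj(np.roll(v.nodes, -r)))
    s_u = float(np.sum(np.abs(u.nodes) ** 2))
    s_v = float(np.sum(np.abs(v.nodes) ** 2))
    return _result_from_correlation(corr, s_u, s_v, N)


class CurveCache:
    """Per-curve precomputations reused across all pairings.

    For each curve the squared norm and two transforms are stored: the FFT
    of the conjugated nodes (used when the curve is the second of a pair)
    and the scaled inverse FFT of the nodes (used when it is the first).
    The product of the two, inverse-transformed, is the full circular
    cross-correlation ``C(r)`` for every shift at once.
    """

    def __init__(self) -> None:
        # keeps a strong reference to each curve: ids must stay unique
        self._store: dict[int, tuple[NormalizedCurve, tuple]] = {}

    def get(self, curve: NormalizedCurve) -> tuple[float, np.ndarray, np.ndarray]:
        key = id(curve)
        hit = self._store.get(key)
        if hit is not None and hit[0] is curve:
            return hit[1]
        nodes = curve.nodes
        s = float(np.sum(np.abs(nodes) ** 2))
        f_second = np.fft.fft(np.conj(nodes))
        f_first = nodes.size * np.fft.ifft(nodes)
        entry = (s, f_second, f_first)
        self._store[key] = (curve, entry)
        return entry


def bam_fast(
    u: NormalizedCurve, v: NormalizedCurve, cache: CurveCache | None = None
) -> AlignmentResult:
    """FFT-accelerated BAM, identical to :func:`bam_brute_force` to 1e-8.

    The circular cross-correlation over all shifts is a single inverse FFT
    of the product of the cached per-curve transforms: O(N log N) per pair.
    """
    _check_pair(u, v)
    cache = cache or CurveCache()
    s_u, _, f_first = cache.get(u)
    s_v, f_second, _ = cache.get(v)
    corr = np.fft.ifft(f_first * f_second)
    return _result_from_correlation(corr, s_u, s_v, u.N)


def bam_distance(
    u: NormalizedCurve,
    v: NormalizedCurve,
    cache: CurveCache | None = None,
    reflection: bool = False,
) -> float:
    """BAM distance, optionally also minimising over reflection."""
    d = bam_fast(u, v, cache).distance
    if reflection:
        v_ref = NormalizedCurve(np.conj(v.nodes)[::-1], source=v.source)
        d = min(d, bam_fast(u, v_ref, cache).distance)
    return d


@dataclass
class DissimilarityMatrix:
    """Symmetric matrix of pairwise BAM distances with its curve index."""

    values: np.ndarray
    curve_index: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        M = self.values.shape[0]
        if self.values.shape != (M, M):
            raise ValueError("dissimilarity matrix must be square")
        if not self.curve_index:
            self.curve_index = [(str(i), 0) for i in range(M)]
        if len(self.curve_index) != M:
            raise ValueError("curve_index length must match matrix size")

    @property
    def M(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """The M(M-1)/2 upper-triangle distances as a flat vector."""
        iu = np.triu_indices(self.M, k=1)
        return self.values[iu]

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("distances", data=self.values)
            ids = np.array([cid for cid, _ in self.curve_index], dtype="S")
            frames = np.array([fr for _, fr in self.curve_index], dtype=int)
            f.create_dataset("cell_id", data=ids)
            f.create_dataset("frame", data=frames)

    @classmethod
    def load(cls, path: str | Path) -> "DissimilarityMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            values = f["distances"][...]
            ids = [s.decode() for s in f["cell_id"][...]]
            frames = [int(x) for x in f["frame"][...]]
        return cls(values=values, curve_index=list(zip(ids, frames)))


def pairwise_matrix(
    curves: Sequence[NormalizedCurve],
    reflection: bool = False,
    chunk: int = 256,
) -> DissimilarityMatrix:
    """Build the full M x M BAM dissimilarity matrix.

    Per-curve transforms are computed once; pairs are evaluated in row
    chunks with batched inverse FFTs.  Both triangles are filled from the
    upper one (BAM is symmetric by construction).
    """
    if len(curves) == 0:
        raise ValueError("pairwise_matrix needs at least one curve")
    N = curves[0].N
    if any(c.N != N for c in curves):
        raise ValueError("all curves must share the same node count")
    M = len(curves)
    nodes = np.stack([c.nodes for c in curves])
    s = np.sum(np.abs(nodes) ** 2, axis=1)
    f_second = np.fft.fft(np.conj(nodes), axis=1)
    f_first = N * np.fft.ifft(nodes, axis=1)
    if reflection:
        refl = np.conj(nodes)[:, ::-1]
        f_second_refl = np.fft.fft(np.conj(refl), axis=1)

    D = np.zeros((M, M), dtype=float)
    for i in range(M):
        js = np.arange(i + 1, M)
        for lo in range(0, js.size, chunk):
            batch = js[lo : lo + chunk]
            corr = np.fft.ifft(f_first[i][None, :] * f_second[batch], axis=1)
            A = np.max(np.abs(corr), axis=1)
            if reflection:
                corr_r = np.fft.ifft(f_first[i][None, :] * f_second_refl[batch], axis=1)
                A = np.maximum(A, np.max(np.abs(corr_r), axis=1))
            raw = np.maximum(s[i] + s[batch] - 2.0 * A, 0.0)
            D[i, batch] = np.sqrt(raw / N)
    D = D + D.T
    index = [c.source for c in curves]
    return DissimilarityMatrix(values=D, curve_index=index)
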