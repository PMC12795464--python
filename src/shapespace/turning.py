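"""Prediction of depolarisation-driven turns from shape-space trajectories.

Migrating cells can change direction by depolarising — retracting the
tail, rounding up — and re-extending in a new direction.  In shape space
this reads as a characteristic loop: polarised (elongated) shapes drift
to the depolarised (round) region and back.  A four-state hidden Markov
model with 2D Gaussian emissions over (dc1, dc2) segments trajectories
into polarised, depolarising, depolarised and repolarising states; a turn
is predicted wherever the decoded sequence shows depolarised →
repolarising → polarised, at the moment polarisation resumes.

Predictions are validated against the real-space centroid track with two
angle checks (a local one for abrupt turns, a distant chord-based one for
gradual turns), a straightness check of inter-turn segments, and a
localisation of the true turn as the point of maximal perpendicular
distance from the segment chord.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from shapespace.curves import DEFAULT_FRAME_INTERVAL
from shapespace.dynamics import ShapeTrajectory

__all__ = [
    "STATE_NAMES",
    "POLARISED",
    "DEPOLARISING",
    "DEPOLARISED",
    "REPOLARISING",
    "TurnModel",
    "train_hmm",
    "decode_states",
    "predict_turns",
    "angle_checks",
    "straightness_check",
    "locate_true_turn",
    "evaluate_predictions",
]

STATE_NAMES = ["polarised", "depolarising", "depolarised", "repolarising"]
POLARISED, DEPOLARISING, DEPOLARISED, REPOLARISING = range(4)


@dataclass
class TurnModel:
    """4-state Gaussian-emission HMM over the (dc1, dc2) plane."""

    means: np.ndarray  # (4, 2)
    covars: np.ndarray  # (4, 2, 2), symmetric positive definite
    transmat: np.ndarray  # (4, 4), rows sum to 1
    startprob: np.ndarray  # (4,)
    state_names: list[str] = field(default_factory=lambda: list(STATE_NAMES))

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, float)
        self.covars = np.asarray(self.covars, float)
        self.transmat = np.asarray(self.transmat, float)
        self.startprob = np.asarray(self.startprob, float)
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        for c in self.covars:
            if not np.allclose(c, c.T) or np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError("emission covariances must be symmetric positive definite")

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    def to_hmmlearn(self):
        from hmmlearn.hmm import GaussianHMM

        h = GaussianHMM(
            n_components=self.n_states,
            covariance_type="full",
            init_params="",
            params="",
        )
        h.startprob_ = self.startprob
        h.transmat_ = self.transmat
        h.means_ = self.means
        h.covars_ = self.covars
        return h

    def save(self, path: str | Path) -> None:
        payload = {
            "state_names": self.state_names,
            "means": self.means.tolist(),
            "covars": self.covars.tolist(),
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TurnModel":
        p = json.loads(Path(path).read_text())
        return cls(
            means=np.array(p["means"]),
            covars=np.array(p["covars"]),
            transmat=np.array(p["transmat"]),
            startprob=np.array(p["startprob"]),
            state_names=list(p["state_names"]),
        )


def train_hmm(
    labelled_sequences: Sequence[tuple[np.ndarray, np.ndarray]],
    n_states: int = 4,
) -> TurnModel:
    """Supervised maximum-likelihood estimation from hand-labelled sequences.

    Each training item is ``(coords, labels)``: an (n, 2) coordinate array
    and per-frame integer state labels.  Emission Gaussians are the sample
    mean/covariance of each state's frames, the transition matrix comes
    from labelled bigram counts with add-one smoothing, and the initial
    distribution from first-frame labels (also smoothed).  Every state
    needs at least two labelled frames for its covariance to exist.
    """
    if not labelled_sequences:
        raise ValueError("at least one labelled sequence is required")
    per_state: list[list[np.ndarray]] = [[] for _ in range(n_states)]
    trans = np.ones((n_states, n_states))  # add-one smoothing
    start = np.ones(n_states)
    for coords, labels in labelled_sequences:
        coords = np.atleast_2d(np.asarray(coords, float))
        labels = np.asarray(labels, int)
        if coords.shape[0] != labels.shape[0]:
            raise ValueError("coords and labels must have equal length")
        for s in range(n_states):
            per_state[s].extend(coords[labels == s])
        start[labels[0]] += 1
        for a, b in zip(labels[:-1], labels[1:]):
            trans[a, b] += 1
    means = np.zeros((n_states, coords.shape[1]))
    covars = np.zeros((n_states, coords.shape[1], coords.shape[1]))
    for s in range(n_states):
        X = np.array(per_state[s])
        if X.shape[0] < 2:
            raise ValueError(
                f"state {STATE_NAMES[s] if s < 4 else s} has {X.shape[0]} labelled "
                "frames; need at least 2 to estimate a covariance"
            )
        means[s] = X.mean(axis=0)
        covars[s] = np.cov(X.T) + 1e-9 * np.eye(coords.shape[1])
    return TurnModel(
        means=means,
        covars=covars,
        transmat=trans / trans.sum(axis=1, keepdims=True),
        startprob=start / start.sum(),
    )


def decode_states(model: TurnModel, traj: ShapeTrajectory | np.ndarray) -> np.ndarray:
    """Viterbi maximum-probability state path for a trajectory."""
    coords = traj.coords if isinstance(traj, ShapeTrajectory) else np.atleast_2d(traj)
    X = np.asarray(coords, float)[:, : model.means.shape[1]]
    _, states = model.to_hmmlearn().decode(X, algorithm="viterbi")
    return states


def predict_turns(states: np.ndarray) -> tuple[list[int], list[tuple[int, int]]]:
    """Turn frames and candidate straight segments from a decoded state path.

    A turn is predicted for every maximal run pattern
    ``depolarised+ repolarising+ polarised``, at the first polarised frame
    (the moment of repolarisation).  Segments between consecutive turns
    and the track ends are the candidate straight segments.
    """
    states = np.asarray(states, int)
    runs: list[tuple[int, int]] = []  # (state, start index)
    for i, s in enumerate(states):
        if not runs or runs[-1][0] != s:
            runs.append((s, i))
    turns: list[int] = []
    for a, b, c in zip(runs, runs[1:], runs[2:]):
        if a[0] == DEPOLARISED and b[0] == REPOLARISING and c[0] == POLARISED:
            turns.append(c[1])
    bounds = [0] + turns + [len(states) - 1]
    segments = [
        (lo, hi) for lo, hi in zip(bounds[:-1], bounds[1:]) if hi > lo
    ]
    return turns, segments


def _vec_angle_deg(v1: np.ndarray, v2: np.ndarray) -> float | None:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return None
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def angle_checks(
    centroids: np.ndarray,
    turn_frame: int,
    local_deg: float = 40.0,
    distant_deg: float = 25.0,
    local_window: int = 2,
    distant_window: int = 6,
) -> dict:
    """Local and distant direction-change checks at a predicted turn.

    The local check compares the short-range incoming and outgoing
    directions (±``local_window`` frames) against ``local_deg``; the
    distant check compares chords over ±``distant_window`` frames against
    ``distant_deg``, catching gradual turns.  A check without enough
    frames on either side is reported as not-evaluable (``None``), not
    failed.  The turn is confirmed if either check passes.
    """
    centroids = np.asarray(centroids, float)
    n = len(centroids)
    out: dict = {}
    for name, w, thr in (
        ("local", local_window, local_deg),
        ("distant", distant_window, distant_deg),
    ):
        if turn_frame - w < 0 or turn_frame + w >= n:
            out[f"{name}_angle"] = None
            out[f"{name}_pass"] = None
            continue
        incoming = centroids[turn_frame] - centroids[turn_frame - w]
        outgoing = centroids[turn_frame + w] - centroids[turn_frame]
        ang = _vec_angle_deg(incoming, outgoing)
        out[f"{name}_angle"] = ang
        out[f"{name}_pass"] = None if ang is None else bool(ang >= thr)
    passes = [out["local_pass"], out["distant_pass"]]
    evaluable = [p for p in passes if p is not None]
    out["confirmed"] = bool(any(evaluable)) if evaluable else None
    return out


def _perp_distances(points: np.ndarray) -> np.ndarray:
    """Perpendicular distance of each point to the first-to-last chord."""
    chord = points[-1] - points[0]
    L = np.linalg.norm(chord)
    if L == 0:
        raise ValueError("degenerate chord: segment endpoints coincide")
    rel = points - points[0]
    return np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / L


def straightness_check(
    segment_centroids: np.ndarray, max_deviation_frac: float = 0.15
) -> dict:
    """Is a track segment straight?

    Passes when the maximal perpendicular deviation from the chord joining
    the segment endpoints is at most ``max_deviation_frac`` of the chord
    length.  Segments shorter than 3 points are not evaluable.
    """
    pts = np.asarray(segment_centroids, float)
    if len(pts) < 3:
        return {"straight": None, "max_deviation": None, "chord_length": None}
    chord_len = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord_len == 0:
        return {"straight": False, "max_deviation": None, "chord_length": 0.0}
    dev = float(_perp_distances(pts).max())
    return {
        "straight": bool(dev <= max_deviation_frac * chord_len),
        "max_deviation": dev,
        "chord_length": chord_len,
    }


def locate_true_turn(
    segment_centroids: np.ndarray, floor_frac: float = 0.05
) -> dict:
    """Locate the real-space turn inside a straight-turn-straight segment.

    The true turn is the interior point with the highest perpendicular
    distance to the chord joining the segment endpoints (ties: earliest
    frame).  If that distance is below ``floor_frac`` of the chord length
    the segment is flagged as having no clear turn.
    """
    pts = np.asarray(segment_centroids, float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points to locate a turn")
    dists = _perp_distances(pts)
    interior = dists[1:-1]
    idx = int(np.argmax(interior)) + 1
    chord_len = float(np.linalg.norm(pts[-1] - pts[0]))
    return {
        "frame": idx,
        "distance": float(dists[idx]),
        "clear": bool(dists[idx] >= floor_frac * chord_len),
    }


def evaluate_predictions(
    predicted: Sequence[Sequence[int]],
    true_turns: Sequence[Sequence[int]],
    track_lengths: Sequence[int] | None = None,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    window_frames: int = 2,
) -> dict:
    """Compare predicted turn frames with ground-truth turns across tracks.

    For each predicted turn the delay to the nearest true turn is recorded
    (frames and minutes); the fraction within ``window_frames`` frames of
    a true turn mirrors a ±(window * frame_interval) minute tolerance.
    Control delays are measured at the midpoints of the path segments
    flanking each true turn, which should sit far from any turn when
    segments are long.  Recall counts a true turn as recovered when a
    prediction lands within the window.
    """
    pred_delays: list[float] = []
    control_delays: list[float] = []
    n_true = 0
    n_true_recovered = 0
    for ti, (preds, trues) in enumerate(zip(predicted, true_turns)):
        preds, trues = list(preds), list(trues)
        n_true += len(trues)
        if trues:
            for p in preds:
                pred_delays.append(min(abs(p - t) for t in trues))
            for t in trues:
                if preds and min(abs(p - t) for p in preds) <= window_frames:
                    n_true_recovered += 1
            length = track_lengths[ti] if track_lengths is not None else None
            bounds = [0] + trues + ([length - 1] if length else [])
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                mid = (lo + hi) // 2
                control_delays.append(min(abs(mid - t) for t in trues))
        else:
            # predictions on a turn-free track are unmatched false positives
            pred_delays.extend([np.inf] * len(preds))
    pred_delays_arr = np.asarray(pred_delays, float)
    control_arr = np.asarray(control_delays, float)
    n_pred = pred_delays_arr.size
    within = pred_delays_arr <= window_frames
    return {
        "n_predictions": int(n_pred),
        "n_true_turns": int(n_true),
        "delays_frames": pred_delays_arr,
        "delays_minutes": pred_delays_arr * frame_interval,
        "fraction_within_window": float(within.mean()) if n_pred else np.nan,
        "false_positive_rate": float(1.0 - within.mean()) if n_pred else np.nan,
        "recall": float(n_true_recovered / n_true) if n_true else np.nan,
        "control_delays_frames": control_arr,
        "control_fraction_within_window": (
            float((control_arr <= window_frames).mean()) if control_arr.size else np.nan
        ),
    }
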