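"""Synthetic cell outlines and migration tracks with known ground truth.

Shapes are built from a star-convex radial profile around the centroid:
an ellipse base (elongation), an optional Gaussian-bump tail at the rear
pole, sinusoidal protrusion lobes, and smooth periodic boundary noise.
Star-convexity guarantees simple (non-self-intersecting) closed curves,
which is sufficient to emulate the morphology classes of migrating
epithelial cells — round, elongated-with-tail, multi-protrusion — even
though strongly re-entrant real shapes are outside its reach.

Migration tracks cycle through the four polarisation states
(polarised → depolarising → depolarised → repolarising → polarised) with
Poisson dwell times, a straight centroid path while polarised, and a new
heading drawn at each repolarisation.  The generator emits per-frame
ground-truth state labels, true turn frames, idealised shape-space
emissions (per-state 2D Gaussians at a configurable separation), and
optionally the corresponding contours — so every downstream module can
be tested end to end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from shapespace.bam import pairwise_matrix
from shapespace.curves import Contour, resample_curve
from shapespace.turning import DEPOLARISED, DEPOLARISING, POLARISED, REPOLARISING

__all__ = [
    "ShapeParams",
    "TrackParams",
    "SyntheticTrack",
    "make_shape",
    "default_classes",
    "make_population",
    "make_migration_tracks",
    "make_shape_walks",
]


@dataclass(frozen=True)
class ShapeParams:
    """Radial-profile parameters of one synthetic cell outline."""

    base_radius: float = 20.0
    elongation: float = 0.0  # major axis = base_radius * (1 + elongation)
    tail_length: float = 0.0  # bump height as a fraction of base_radius
    tail_width: float = 0.35  # angular width (radians) of the tail bump
    n_protrusions: int = 0
    protrusion_amplitude: float = 0.0  # fraction of base_radius
    boundary_noise_sd: float = 0.0  # fraction of base_radius
    n_points: int = 200
    seed: int | None = None


def _radial_profile(p: ShapeParams, phi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    a = p.base_radius * (1.0 + p.elongation)
    b = p.base_radius
    rho = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    if p.tail_length > 0:
        dphi = np.angle(np.exp(1j * (phi - np.pi)))  # wrapped distance to rear pole
        rho = rho + p.tail_length * p.base_radius * np.exp(-((dphi / p.tail_width) ** 2))
    if p.n_protrusions > 0 and p.protrusion_amplitude > 0:
        centers = 2 * np.pi * np.arange(p.n_protrusions) / p.n_protrusions + 0.4
        for c in centers:
            dphi = np.angle(np.exp(1j * (phi - c)))
            rho = rho + p.protrusion_amplitude * p.base_radius * np.exp(
                -((dphi / 0.25) ** 2)
            )
    if p.boundary_noise_sd > 0:
        # smooth periodic noise from a handful of random low-order modes
        modes = np.arange(2, 9)
        amp = rng.normal(size=modes.size) * p.boundary_noise_sd * p.base_radius
        phase = rng.uniform(0, 2 * np.pi, size=modes.size)
        rho = rho + (amp[:, None] * np.cos(modes[:, None] * phi[None, :] + phase[:, None])).sum(
            axis=0
        ) / np.sqrt(modes.size)
    return rho


def make_shape(
    p: ShapeParams,
    rng: np.random.Generator | None = None,
    center: tuple[float, float] = (0.0, 0.0),
    heading: float = 0.0,
    cell_id: str = "0",
    frame: int = 0,
    frame_interval: float = 5.0,
) -> Contour:
    """Generate one star-convex cell-like contour.

    ``heading`` rotates the whole profile so the tail points opposite the
    direction of motion.  If the drawn boundary noise makes the radial
    profile non-positive, the noise is halved and redrawn (at most 10
    attempts) so the output is always a valid simple curve.
    """
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    phi = 2 * np.pi * np.arange(p.n_points) / p.n_points
    params = p
    for _ in range(10):
        rho = _radial_profile(params, phi, rng)
        if np.all(rho > 0.05 * p.base_radius):
            ang = phi + heading
            pts = np.column_stack(
                [center[0] + rho * np.cos(ang), center[1] + rho * np.sin(ang)]
            )
            return Contour(
                points=pts, cell_id=cell_id, frame=frame, frame_interval=frame_interval
            )
        params = replace(
            params,
            boundary_noise_sd=params.boundary_noise_sd * 0.5,
            protrusion_amplitude=params.protrusion_amplitude * 0.5,
        )
    raise RuntimeError("could not generate a simple curve after 10 attempts")


def default_classes() -> list[ShapeParams]:
    """Three well-separated morphology classes: round, tailed, multi-protrusion."""
    return [
        ShapeParams(elongation=0.05, boundary_noise_sd=0.01),
        ShapeParams(elongation=1.8, tail_length=1.0, boundary_noise_sd=0.01),
        ShapeParams(
            elongation=0.1,
            n_protrusions=5,
            protrusion_amplitude=0.8,
            boundary_noise_sd=0.01,
        ),
    ]


def _jitter(p: ShapeParams, rng: np.random.Generator, scale: float) -> ShapeParams:
    g = lambda: float(np.exp(rng.normal(0.0, scale)))
    return replace(
        p,
        base_radius=p.base_radius * g(),
        elongation=p.elongation * g(),
        tail_length=p.tail_length * g(),
        protrusion_amplitude=p.protrusion_amplitude * g(),
    )


def make_population(
    classes: Sequence[ShapeParams],
    n_per_class: int,
    seed: int = 0,
    jitter: float = 0.08,
    separation_factor: float = 3.0,
    check_nodes: int = 128,
    max_retries: int = 3,
) -> tuple[list[Contour], np.ndarray]:
    """Labelled population of shapes with guaranteed class separation.

    Within-class variation comes from log-normal parameter jitter.  After
    generation the mean between-class BAM distance is checked to exceed
    the mean within-class distance by ``separation_factor``; failing
    draws are retried with a fresh sub-seed and an error is raised if the
    requested separation cannot be achieved.
    """
    if len(classes) < 1:
        raise ValueError("at least one shape class is required")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + 1000 * attempt)
        contours: list[Contour] = []
        labels: list[int] = []
        for ci, cls in enumerate(classes):
            for i in range(n_per_class):
                c = make_shape(
                    _jitter(cls, rng, jitter),
                    rng,
                    cell_id=f"c{ci}_{i}",
                    heading=rng.uniform(0, 2 * np.pi),
                )
                contours.append(c)
                labels.append(ci)
        lab = np.array(labels)
        if len(classes) == 1:
            return contours, lab
        curves = [resample_curve(c, check_nodes) for c in contours]
        D = pairwise_matrix(curves).values
        same = lab[:, None] == lab[None, :]
        iu = np.triu_indices(len(lab), k=1)
        within = D[iu][same[iu]]
        between = D[iu][~same[iu]]
        if between.mean() >= separation_factor * within.mean():
            return contours, lab
    raise RuntimeError(
        f"could not achieve {separation_factor}x between/within BAM separation "
        f"after {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# Migration tracks with polarisation cycles

# idealised shape-space layout of the four states (arbitrary units):
# polarised far out on dc1, depolarised at the origin, the two transition
# states between them, split along dc2
_STATE_LAYOUT = np.array(
    [
        [3.0, 0.0],  # polarised
        [1.5, 0.8],  # depolarising
        [0.0, 0.0],  # depolarised
        [1.5, -0.8],  # repolarising
    ]
)

_STATE_SHAPES = {
    POLARISED: ShapeParams(elongation=1.6, tail_length=0.9, boundary_noise_sd=0.015),
    DEPOLARISING: ShapeParams(elongation=0.7, tail_length=0.4, boundary_noise_sd=0.015),
    DEPOLARISED: ShapeParams(elongation=0.08, boundary_noise_sd=0.015),
    REPOLARISING: ShapeParams(elongation=0.7, tail_length=0.1, boundary_noise_sd=0.015),
}


@dataclass(frozen=True)
class TrackParams:
    """Parameters of the synthetic polarisation-cycle track generator."""

    n_frames: int = 60
    frame_interval: float = 5.0
    dwell_means: tuple[float, float, float, float] = (10.0, 3.0, 4.0, 3.0)
    min_dwell: int = 2
    polarised_speed: float = 3.0  # centroid displacement per frame while polarised
    transition_speed_frac: float = 0.3  # fraction of polarised speed in transitions
    jiggle_sd: float = 0.0  # isotropic centroid noise, all states
    turn_deg_range: tuple[float, float] = (60.0, 170.0)
    emission_separation: float = 3.0  # min distance between state means, in sd units
    seed: int = 0


@dataclass
class SyntheticTrack:
    """One generated track with complete ground truth."""

    track_id: str
    frames: np.ndarray
    centroids: np.ndarray
    states: np.ndarray  # per-frame ground-truth state index
    true_turns: list[int]  # frames where a new heading takes effect
    emissions: np.ndarray  # idealised (dc1, dc2) shape-space trajectory
    frame_interval: float
    contours: list[Contour] = field(default_factory=list)


def _emission_sd(separation: float) -> float:
    d = np.linalg.norm(
        _STATE_LAYOUT[:, None, :] - _STATE_LAYOUT[None, :, :], axis=2
    )
    min_sep = d[d > 0].min()
    return float(min_sep / separation)


def make_migration_tracks(
    p: TrackParams,
    n_tracks: int = 10,
    make_contours: bool = False,
) -> list[SyntheticTrack]:
    """Generate tracks cycling through the four polarisation states.

    The centroid moves straight at ``polarised_speed`` while polarised,
    creeps during transitions, and is stationary (up to ``jiggle_sd``)
    while depolarised.  At every repolarised → polarised transition a new
    heading is drawn with a turn magnitude from ``turn_deg_range`` (random
    sign); that first polarised frame is a ground-truth turn.  Shape-space
    emissions are drawn from per-state isotropic Gaussians whose means are
    ``emission_separation`` standard deviations apart at the closest pair.
    """
    rng = np.random.default_rng(p.seed)
    sd = _emission_sd(p.emission_separation)
    tracks: list[SyntheticTrack] = []
    cycle = [POLARISED, DEPOLARISING, DEPOLARISED, REPOLARISING]
    for ti in range(n_tracks):
        states = np.empty(p.n_frames, dtype=int)
        phase = 0
        f = 0
        # start mid-way through a polarised dwell so turns are interior
        while f < p.n_frames:
            s = cycle[phase % 4]
            dwell = max(p.min_dwell, int(rng.poisson(p.dwell_means[s])))
            states[f : f + dwell] = s
            f += dwell
            phase += 1
        heading = rng.uniform(0, 2 * np.pi)
        pos = np.zeros(2)
        centroids = np.empty((p.n_frames, 2))
        headings = np.empty(p.n_frames)
        true_turns: list[int] = []
        for f in range(p.n_frames):
            s = states[f]
            if f > 0 and s == POLARISED and states[f - 1] == REPOLARISING:
                mag = np.radians(rng.uniform(*p.turn_deg_range))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                heading = heading + sign * mag
                true_turns.append(f)
            if s == POLARISED:
                step = p.polarised_speed
            elif s == DEPOLARISED:
                step = 0.0
            else:
                step = p.polarised_speed * p.transition_speed_frac
            pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
            if p.jiggle_sd > 0:
                pos = pos + rng.normal(0.0, p.jiggle_sd, size=2)
            centroids[f] = pos
            headings[f] = heading
        emissions = _STATE_LAYOUT[states] + rng.normal(0.0, sd, size=(p.n_frames, 2))
        contours: list[Contour] = []
        if make_contours:
            for f in range(p.n_frames):
                contours.append(
                    make_shape(
                        _STATE_SHAPES[states[f]],
                        rng,
                        center=tuple(centroids[f]),
                        heading=headings[f],
                        cell_id=f"t{ti}",
                        frame=f,
                        frame_interval=p.frame_interval,
                    )
                )
        tracks.append(
            SyntheticTrack(
                track_id=f"t{ti}",
                frames=np.arange(p.n_frames),
                centroids=centroids,
                states=states,
                true_turns=true_turns,
                emissions=emissions,
                frame_interval=p.frame_interval,
                contours=contours,
            )
        )
    return tracks


def make_shape_walks(
    n_tracks: int = 20,
    n_steps: int = 50,
    step_scale: float = 1.0,
    retraction_speed_factor: float = 1.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Random walks in the (dc1, dc2) plane with direction-dependent speed.

    Step directions are uniform on the circle and lengths Rayleigh with
    scale ``step_scale`` (the isotropic 2D Gaussian step model, mean step
    length ``step_scale * sqrt(pi / 2)``); steps pointing backwards along
    dc1 (the retraction sector, 135–225 degrees) are stretched by
    ``retraction_speed_factor``, emulating faster tail retraction than
    elongation.  Returns per-track coordinate arrays.
    """
    rng = np.random.default_rng(seed)
    walks = []
    for _ in range(n_tracks):
        ang = rng.uniform(-np.pi, np.pi, size=n_steps)
        length = rng.rayleigh(step_scale, size=n_steps) + 1e-12
        deg = np.degrees(ang) % 360.0
        retr = (deg >= 135.0) & (deg < 225.0)
        length[retr] *= retraction_speed_factor
        steps = np.column_stack([length * np.cos(ang), length * np.sin(ang)])
        walks.append(np.vstack([np.zeros(2), np.cumsum(steps, axis=0)]))
    return walks
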