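# Methods

This note records the models implemented in `shapespace`, the numerical
choices behind them, and what the synthetic benchmarks do and do not
demonstrate.

## Curve normalisation

A contour enters as an ordered point list; closure is implicit. Before
any distance is computed the curve is put into canonical form:

- traversal is forced counter-clockwise (positive signed area). The
  alignment metric's cross-correlation assumes a consistent traversal
  direction; fixing it canonically makes stored representations
  deterministic without affecting distances.
- node 0 is kept at the input's first vertex. The metric optimises over
  cyclic shifts, so this choice only affects reproducibility of the
  stored arrays, never a distance.
- N nodes (default 512, minimum 8) are placed at equal arc-length steps
  and the node mean is translated to the origin. Equal steps measured
  along the *source* polygon do not give exactly equal chords on the
  *output* polygon (chords shorten where curvature concentrates), so the
  re-chording is iterated to its fixed point (tolerance 1e-10 of the
  curve scale, at most 50 sweeps). This makes resampling idempotent to
  well below 1e-6 and gives a self-consistent "equally spaced" invariant.
- no scale normalisation: size is genuine shape information (area is a
  reported feature), so curves are compared at their native scale.

512 nodes resolve typical cell outlines; the node count is a parameter
everywhere. Accuracy of the resampled representation depends on the
input sampling density — a circle given by ~1000 irregularly spaced
vertices is recovered to about 1e-3 of its radius; sparser polygons
carry a chordal error of order (vertex spacing)²/radius that no
resampler can undo.

Mask input is traced with a sub-pixel marching-squares contour on a
Gaussian-smoothed (σ = 1 px) indicator image; the smoothing removes the
pixel staircase whose 8-connected path length would otherwise
overestimate perimeters by several percent.

## Best-alignment metric

For canonical curves u, v the squared distance is the minimum over plane
rotation θ and cyclic shift r of the mean squared node difference
(translation was already removed by centering; see the module docstring
for the formula). Two facts make it fast:

1. at fixed r the optimal rotation is θ* = arg C(r), where
   C(r) = Σⱼ uⱼ·conj(v_{j+r}) is the circular cross-correlation, leaving
   s(u) + s(v) − 2·max_r |C(r)| with s(·) the squared node norm;
2. all N values of C(r) come from a single inverse FFT of the product of
   two per-curve transforms.

The per-curve transforms and norms are cached, so an M×M matrix costs
one FFT pair per curve plus one inverse FFT per pair. A brute-force
O(N²) implementation is retained as the oracle; the two agree to ~1e-15
on random curves, and the test suite pins them together at 1e-8.

Numerical notes:

- when several shifts attain the maximum modulus, the smallest r wins
  (first argmax), making results deterministic;
- the raw squared distance s(u)+s(v)−2A can go slightly negative from
  rounding; values above −1e-9 (relative) are clamped to zero, anything
  more negative raises, since it signals a transform inconsistency;
- the achievable "zero" of the distance is √(ε/N) ≈ 1e-8–1e-7 in double
  precision because of the final square root, which is why exact-match
  assertions use a 1e-7 floor;
- the reported alignment (shift, rotation) applies to the **second**
  curve: `exp(iθ)·roll(v, −r)` lands v on u at the reported distance.

Reflection is not quotiented out by default — mirror-image shapes (left-
versus right-turning cells) must stay distinct. An optional reflection
mode also compares against the conjugated, reversed curve and keeps the
minimum.

The matrix is built dense. At 512 nodes and 64-bit floats this is
comfortable to M ≈ 20,000 on a workstation; the row-chunked inner loop
(256 rows per batch) keeps peak memory flat, and the same chunking would
back an on-disk store for larger surveys.

## Diffusion-map embedding

Distances become affinities through a Gaussian kernel with bandwidth σ
set to the median off-diagonal distance — a robust "contextual scale"
that needs no tuning. The affinity matrix is row-normalised into a
Markov operator P (density-correction exponent α ∈ {0, ½, 1} is
available; the default α = 0 is the plain construction). Eigenpairs are
computed through the symmetric conjugate D^{1/2} P D^{-1/2}, which has
the same spectrum and orthogonal eigenvectors; the trivial constant
eigenvector (eigenvalue 1) is dropped and coordinate i is λᵢψᵢ
(diffusion time t = 1). Eigenvector signs are fixed by making the
largest-magnitude entry positive so runs and solvers agree. A sparse
path thresholds affinities below 1e-12 and uses an iterative eigensolver
with a seeded start vector.

The absolute scale of diffusion coordinates is meaningless (it depends
on M through eigenvector normalisation); every downstream analysis uses
relative positions only.

"Variance captured" by the first m coordinates is defined as
Σ_{i≤m} λᵢ² / Σ_{i≤k} λᵢ² over the k retained non-trivial eigenvalues —
the diffusion-distance energy fraction. Alternative conventions (|λ|,
kernel spectrum) would give different numbers; this one is monotone,
lies in [0, 1], and matches the intuition that coordinates contribute
quadratically to diffusion distances.

## Out-of-sample extension

New shapes are placed into a learned space without re-embedding:

- **K-NN** (default K = 5): unweighted mean of the diffusion coordinates
  of the K nearest training shapes by BAM distance. K = 1 restricted to
  training curves is exactly the identity.
- **Laplacian pyramid**: multiscale kernel regression with bandwidths
  σ, σ/2, σ/4, …, each level fitting the residual of the previous ones;
  the halving schedule stops when the training residual stops
  decreasing (at most 12 levels). On training inputs the pyramid
  reproduces coordinates to well within 5% of the coordinate scale.
  The 5% tolerance is stated against the overall coordinate scale, not
  per component — a relative error on a near-zero coordinate would be
  meaningless. Queries whose nearest training shape is further than 10σ
  are flagged as low-confidence extrapolations.

## Shape features

Sixteen classical descriptors interpret the abstract coordinates.
Polygon area, centroid and second moments come from the exact shoelace
(Green's theorem) formulas; the ellipse quantities (major/minor axis,
eccentricity, orientation) from the second-moment ellipse; solidity from
the convex hull. Conventions that needed a decision:

- **circularity** = P²/(4πA): 1 for a circle, growing with elongation
  and boundary complexity, so it correlates *positively* with
  elongation (the inverse convention 4πA/P² would flip every sign);
- **eccentricity** is the standard ellipse eccentricity √(1 − (b/a)²),
  0 for a circle, → 1 with elongation;
- **extent** is measured against the bounding box aligned with the
  principal axes, not the image axes — otherwise the feature would
  depend on the cell's orientation, and all features except orientation
  itself are deliberately rigid-motion invariant;
- **symmetry** = 1 − d(u, mirror(u)) / (2·rms-radius): 1 for mirror-
  symmetric shapes, decreasing with chirality. **irregularity** is the
  max/mean centre-distance ratio; **irregularity2** the perimeter-
  normalised total absolute deviation of the polygon turning angle from
  a circle's (0 for a circle). These three are documented stand-ins
  behind a stable interface; any replacement only needs to preserve the
  monotonicity the tests pin down.
- centre distances are measured from the boundary centroid; when the
  original contour vertices are available they are used directly, since
  they carry no resampling error.

Feature–coordinate association uses the plain Pearson correlation per
(feature, coordinate) pair; a zero-variance feature reports NaN
(undefined), never 0.

## Exploring the space

- **Grid slicing**: equal-width slices of the (dc1, dc2) ranges,
  half-open intervals with the top slice closed, so boundary shapes are
  counted exactly once.
- **Affinity propagation + hierarchy**: AP runs on negated squared
  distances with the classic median-similarity preference, damping 0.9,
  up to 1000 iterations; exemplars are then grouped by average-linkage
  hierarchical clustering cut at the requested number of groups, and
  the dendrogram leaf order doubles as a seriation for display. This
  clustering sees only raw distances, never the embedding, so agreement
  between cluster structure and the map is an independent check.
- **SOM zoning**: a small rectangular self-organising map (written here
  — no SOM library is part of the dependency set) trained online on
  (dc1, dc2) with exponentially decaying learning rate (0.5 → 0.01) and
  neighbourhood radius (half the grid → 0.5) over 40 epochs, seeded and
  fully deterministic; zones are the Voronoi cells of the prototypes.
- **Group analysis**: per-condition fractions of shapes across regions,
  rows summing to 1, with counts reported alongside.

## Shape dynamics

Trajectories live in the (dc1, dc2) plane; higher coordinates are
ignored in dynamics, matching how the space is read. Speeds are step
norms per frame interval (default 5 minutes per frame). Step directions
are binned from −π in equal sectors; zero-length steps carry no
direction and are excluded but counted. In the high-dc1 territory of
tailed shapes, steps with direction in [−45°, 45°) are elongation
events and [135°, 225°) retraction events — half-open on both so no
step is double-counted. The region bounds are a user input with a
documented default (upper half of the observed dc1 range). Two-sample
comparisons use the Kruskal–Wallis test with medians and means reported.

## Turn prediction

A 4-state HMM (polarised, depolarising, depolarised, repolarising) with
2D full-covariance Gaussian emissions over (dc1, dc2):

- **training is supervised** — per-state sample means/covariances,
  bigram transition counts with add-one smoothing, smoothed first-frame
  initial distribution — because the model is meant to be fit from a
  handful of hand-classified sequences. Every state needs ≥ 2 labelled
  frames; a tiny ridge (1e-9) keeps covariances invertible.
  (Unsupervised Baum–Welch refinement could be layered on top but is
  deliberately not the default.)
- **decoding** is the Viterbi path (via `hmmlearn`; the test suite
  cross-checks it against exhaustive path enumeration on short
  sequences).
- **turn rule**: each maximal run pattern depolarised⁺ repolarising⁺
  polarised predicts one turn at the first polarised frame — the moment
  of repolarisation. Segments between consecutive turns and track ends
  are candidate straight segments.

Geometric validation against the real-space centroid track:

- **local angle check** (threshold 40°, window ±2 frames) compares
  short-range incoming/outgoing directions — catches abrupt turns;
- **distant angle check** (threshold 25°, window ±6 frames) compares
  chords over a longer span — catches gradual turns; a turn is
  confirmed if either passes, and a check without enough frames is
  *not evaluable* rather than failed;
- **straightness**: a segment passes if its maximal perpendicular
  deviation from the endpoint chord is ≤ 15% of the chord length;
- **true turn location**: the interior point with maximal perpendicular
  distance to the endpoint chord (ties → earliest); below 5% of the
  chord length the segment is flagged as having no clear turn.

The angle windows and the straightness/floor fractions are configurable
defaults, chosen once as reasonable geometry at a 5-minute frame
interval; the 40°/25° thresholds are fixed. Evaluation measures, per
prediction, the delay to the nearest true turn, the fraction within a
±2-frame (±10 minute) window, and — as a negative control — the same
delay measured at the midpoints of the straight segments flanking each
true turn.

## Synthetic data

The generator exists so every module is testable without external data,
and its defaults define the benchmark conditions:

- **shapes** are star-convex radial profiles: an ellipse base
  (elongation = major/minor − 1), a Gaussian tail bump at the rear pole
  (length up to ~1 radius, angular width 0.35 rad), up to a handful of
  protrusion lobes, and smooth periodic boundary noise from random
  low-order Fourier modes. Star-convexity guarantees simple curves by
  construction. Default base radius 20 (pixel-like units), 200 boundary
  points.
- **populations**: three default classes — round, elongated-with-tail,
  multi-protrusion — with log-normal parameter jitter (sd 0.08), 20
  shapes per class in the benchmarks; a post-hoc check requires the
  mean between-class BAM distance to exceed 3× the mean within-class
  distance, retrying with fresh sub-seeds and erroring if impossible.
- **tracks** (default 60 frames at 5 min/frame) cycle through the four
  polarisation states with Poisson dwells (means 10/3/4/3 frames,
  minimum 2); the centroid moves 3 units/frame while polarised, creeps
  at 30% through transitions, and rests while depolarised; each
  repolarisation draws a turn of 60–170° with random sign. Shape-space
  emissions come from per-state isotropic Gaussians whose means are
  3 standard deviations apart at the closest pair ("3σ separation").
  Benchmarks train on 10 tracks and decode 100.

What passing these benchmarks shows — and does not. The metric,
embedding, feature and dynamics results are exact or distributional
properties and transfer directly. The turn-prediction results show the
pipeline is correct and near-perfect *when the four states are really
3σ-separated Gaussians in shape space and every turn follows the
depolarisation route*; real cells turn through at least three other
morphological routes, their state clusters overlap far more, and
segmentation noise propagates into the coordinates, so real-data
accuracy is necessarily lower. Star-convex synthetic shapes also cannot
produce strongly re-entrant outlines (hooks, C-shapes), so the
benchmarks do not probe the metric's behaviour there.

## Problem sizes

Benchmarks and tests are sized for a laptop-class run: 60-shape
populations (1,770 pairs), 128-node curves where the full 512 would add
nothing to the property under test, 1,000 metric triples, 10,000-step
walks, 110 HMM tracks. The full suite runs in a few seconds; the
acceptance script in under a minute. An M ≈ 37,800-shape survey — some
1.4 × 10⁹ pairwise comparisons — is the scale the dense-matrix design
targets on a large workstation.

## Known limitations

- Mean-shift (or any) image segmentation is out of scope; masks must
  come segmented, and only the outer boundary of the largest component
  per label is traced.
- Dense distance matrix: memory is O(M²).
- The SOM is a minimal implementation (online training, rectangular
  grid, Gaussian neighbourhood) intended for zoning small 2D embeddings,
  not a general SOM toolkit.
- `variance_captured` depends on the documented eigenvalue-energy
  convention; numbers are not comparable across conventions.
- Only the depolarisation turning mode is modelled; front-drift,
  front-splitting and side-protrusion turns are invisible to the
  4-state HMM by design.
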