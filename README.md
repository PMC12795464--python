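# shapespace

Landmark-free shape-space mapping and shape-dynamics analysis for
migrating cells.

Time-lapse microscopy of mesenchymal cells produces thousands of
segmented outlines whose morphologies vary too widely for a fixed set of
shape descriptors. `shapespace` builds a quantitative map of that
variation directly from the outlines: a fast alignment-based distance
between closed planar curves, a diffusion-map embedding of the pairwise
distance matrix, tools to slice, cluster and compare the embedded space,
statistics of how cells move through it along their tracks, and a hidden
Markov model that predicts depolarisation-driven turns of migrating
cells from their shape trajectory alone.

## The core metric

Each outline is resampled to N equally spaced complex nodes
u₀, …, u_{N−1} with zero mean (N = 512 by default). The distance between
two curves u, v is the best-alignment metric

    d(u, v)² = (1/N) · min_{r, θ}  Σⱼ | uⱼ − e^{iθ} v_{j+r} |²

minimised over plane rotation θ and cyclic node shift r (translation is
removed by centering). For each shift the optimal rotation is analytic,
so the whole search reduces to the modulus of the circular
cross-correlation Σⱼ uⱼ·conj(v_{j+r}), evaluated for all N shifts at once
with one FFT pair — O(N log N) per pair of curves, with per-curve
transforms cached across an M×M matrix build. Reflection is deliberately
not quotiented out, so left- and right-turning cells stay
distinguishable (an optional reflection mode exists).

The distance matrix feeds a Gaussian kernel, ω = exp(−d²/2σ²) with σ the
median pairwise distance, whose row-normalised Markov operator is
eigendecomposed; the leading non-trivial eigenvectors (scaled by their
eigenvalues) are the diffusion coordinates. In cell data the first
coordinate captures elongation and the second irregularity.

## Worked example

```python
import numpy as np
from shapespace import (
    resample_curve, pairwise_matrix, train_hmm, decode_states, predict_turns,
)
from shapespace.embedding import embed_distances
from shapespace import synthetic

# three morphology classes: round, elongated-with-tail, multi-protrusion
contours, labels = synthetic.make_population(
    synthetic.default_classes(), n_per_class=20, seed=1
)
curves = [resample_curve(c, 128) for c in contours]
D = pairwise_matrix(curves)              # 60 x 60 BAM distances
space = embed_distances(D, k=5)          # diffusion-map coordinates
print(np.round(space.eigenvalues, 4))
# [1.     0.6655 0.1676 0.0501 0.0062 0.0033]

# tracks with known polarisation cycles; predict the turns
tracks = synthetic.make_migration_tracks(synthetic.TrackParams(seed=3), 20)
model = train_hmm([(t.emissions, t.states) for t in tracks[:10]])
turns, _ = predict_turns(decode_states(model, tracks[10].emissions))
print(turns, tracks[10].true_turns)
# [24, 44] [24, 44]
```

The eigenvalue list starts with the trivial Markov eigenvalue 1; the gap
after the first two non-trivial values is why two coordinates carry most
of the shape variation here. In the last line the turn frames decoded
from shape information alone coincide with the generator's ground-truth
turns.

The same pipeline is scriptable from the shell:

```
shapespace simulate population --out work --seed 1
shapespace normalize --in work/population.csv --out work/curves.h5 --nodes 128
shapespace bam-matrix --curves work/curves.h5 --out work/D.h5
shapespace embed --matrix work/D.h5 --out work/space.h5 --k 5
shapespace features --curves work/curves.h5 --out work/features.csv
```

## Documentation

`docs/methods.md` describes the model, the numerical choices and the
limits of what the synthetic benchmarks demonstrate.
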