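import numpy as np
import pytest

from shapespace import pairwise_matrix, resample_curve
from shapespace.curves import NormalizedCurve
from shapespace.embedding import embed_distances
from shapespace import synthetic


def random_curve(rng: np.random.Generator, n: int = 32) -> NormalizedCurve:
    """A random zero-mean complex node sequence (not geometrically smooth)."""
    nodes = rng.normal(size=n) + 1j * rng.normal(size=n)
    nodes -= nodes.mean()
    return NormalizedCurve(nodes)


def circle_curve(radius: float = 1.0, n: int = 512, phase: float = 0.0) -> NormalizedCurve:
    j = np.arange(n)
    return NormalizedCurve(radius * np.exp(1j * (phase + 2 * np.pi * j / n)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def population():
    """Three well-separated morphology classes, 20 shapes each."""
    contours, labels = synthetic.make_population(
        synthetic.default_classes(), n_per_class=20, seed=1
    )
    curves = [resample_curve(c, 128) for c in contours]
    return contours, curves, labels


@pytest.fixture(scope="session")
def population_matrix(population):
    _, curves, _ = population
    return pairwise_matrix(curves)


@pytest.fixture(scope="session")
def population_space(population_matrix):
    return embed_distances(population_matrix, k=5)
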