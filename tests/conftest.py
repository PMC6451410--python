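import itertools

import numpy as np
import pytest

from mapkinfo.mi import GaussianMixture
from mapkinfo.surrogate import SurrogateSpec, generate_dataset
from mapkinfo.theory import all_sequences


@pytest.fixture(scope="session")
def cube_mixture() -> GaussianMixture:
    """Eight overlapping 3-D Gaussians at unit-cube vertices (MI ~ 1.8 bit)."""
    verts = np.array(list(itertools.product([0.0, 1.0], repeat=3)))
    return GaussianMixture(means=verts, sigma=0.42)


@pytest.fixture(scope="session")
def s_curve_mixture() -> GaussianMixture:
    """Eight overlapping 3-D Gaussians centred along an S-shaped curve.

    The curve is our own fixture: (sin(pi*t), 2t-1, t^2) for t in [0, 1];
    only the estimator-bias property is asserted against it, not a value.
    """
    t = np.linspace(0.0, 1.0, 8)
    means = np.stack([np.sin(np.pi * t), 2 * t - 1, t**2], axis=1)
    return GaussianMixture(means=means, sigma=0.35)


@pytest.fixture(scope="session")
def hard_limit_dataset():
    """Noise-free surrogate channel for all 16 length-4 sequences at T=30."""
    spec = SurrogateSpec(miss_width=0.0, cell_cv=0.0)
    return generate_dataset(all_sequences(4), 30.0, spec, M=300, seed=11)
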