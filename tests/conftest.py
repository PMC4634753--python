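import numpy as np
import pytest

from serialfreq.coalsim import SimParams, simulate_frequency_matrices
from serialfreq.sitefreq import SamplingDesign, SiteFrequencyMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def design3():
    """Three timepoints 400 generations apart (the ABC study design)."""
    return SamplingDesign.from_times([0, 400, 800])


def random_freq_matrix(rng, n_sites, label, depth=20):
    """A random but valid frequency matrix (integer counts at fixed depth)."""
    counts = rng.multinomial(depth, rng.dirichlet(np.ones(4)), size=n_sites).astype(float)
    return SiteFrequencyMatrix(timepoint=label, counts=counts,
                               depth=np.full(n_sites, float(depth)))


@pytest.fixture
def random_matrices3(rng, design3):
    return [random_freq_matrix(rng, 60, lab) for lab in design3.labels]


@pytest.fixture
def coalsim_matrices3(design3):
    """One simulated dataset at the study's true parameters (3tp x 40 x 1000)."""
    params = SimParams.make(N=3000, mu=1e-5, times=design3.times,
                            n_per_timepoint=40, n_sites=1000, seed=99)
    return simulate_frequency_matrices(params)
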