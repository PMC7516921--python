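import numpy as np
import pytest

from gofselect import NoiseSpec

PAPER_NOISES = {
    "gaussian": NoiseSpec.gaussian(0.0, 3.0),
    "uniform": NoiseSpec.uniform(-1.0, 1.0),
    "poisson": NoiseSpec.poisson(10.0),
    "gamma": NoiseSpec.gamma(3.0, 2.0),
}


@pytest.fixture(params=list(PAPER_NOISES), ids=list(PAPER_NOISES))
def paper_noise(request):
    """One of the four benchmark noise parameterisations."""
    return PAPER_NOISES[request.param]


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
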