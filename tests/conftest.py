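import numpy as np
import pytest

from pofig import EffectSizeDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def crohn_prior():
    """Prior proportion of non-susceptibility loci used in the worked example."""
    return 1.0 - 142 / 12877


@pytest.fixture
def exp_noncentrality_prior():
    """Exponential noncentrality prior of the worked example (mean 17.25)."""
    return EffectSizeDistribution.gamma_prior(1.0, 17.25)
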