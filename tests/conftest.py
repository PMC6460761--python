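import numpy as np
import pytest

from pstfst.pst_model import McmcConfig, ModelSpec
from pstfst.synthetic_data import drift_preset, gen_traits


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def quick_cfg():
    """Short chains for simulation tests; 2 chains x 200 retained draws."""
    return McmcConfig(n_chains=2, burn_in=400, n_iter=400, thin=2, seed=11)


@pytest.fixture
def shared_spec():
    return ModelSpec(trait="call_khz", sex_effect="shared")


@pytest.fixture
def drift_traits():
    return gen_traits(drift_preset(seed=42))
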