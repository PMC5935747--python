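import numpy as np
import pytest

import sigrow as sg


@pytest.fixture(scope="session")
def sunflower():
    return sg.crop_fixture("sunflower")


@pytest.fixture(scope="session")
def all_crops():
    return sg.list_crops()


@pytest.fixture(scope="session")
def noiseless_sunflower_series(sunflower):
    """30 noiseless observations on an even grid spanning [t_b, t_e]."""
    p = sunflower.nsg_params
    return sg.simulate_series(p, np.linspace(p.t_b, p.t_e, 30),
                              label="sunflower")


@pytest.fixture(scope="session")
def sunflower_nsg_fit(noiseless_sunflower_series):
    """One seeded NSG fit of the noiseless sunflower series, shared by tests."""
    return sg.NSGModel(noiseless_sunflower_series).fit(seed=1)
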