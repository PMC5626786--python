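import warnings

import numpy as np
import pytest

from nusrd.acquisition import GridSpec, synthesize_fid
from nusrd.systems import CpmgSeriesSpec, ExchangeSite, ExchangeSystem, make_system

# quantification deliberately warns on boundary maxima etc.; keep test output
# readable without hiding warnings from the code under test entirely
warnings.filterwarnings("ignore", message="peak .*boundary")


@pytest.fixture(scope="session")
def spec_15n():
    return CpmgSeriesSpec(nucleus="15N")


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(n_direct=32, sw_direct_hz=900.0, n_indirect=(32,),
                    sw_indirect_hz=(2250.0,))


@pytest.fixture(scope="session")
def grid_2d():
    return GridSpec(n_direct=64, sw_direct_hz=900.0, n_indirect=(48,),
                    sw_indirect_hz=(2250.0,))


@pytest.fixture(scope="session")
def grid_3d_small():
    return GridSpec(n_direct=32, sw_direct_hz=900.0, n_indirect=(16, 12),
                    sw_indirect_hz=(2250.0, 1400.0),
                    nuclei=("1H", "15N", "13CO"))


@pytest.fixture(scope="session")
def one_site_system():
    site = ExchangeSite("R001", (0.1, 2.0), (20.0, 10.0), 10.0, 0.0, 1.0)
    return ExchangeSystem([site], kex=0.0, p_b=0.0, flat=True)


@pytest.fixture(scope="session")
def sh3_system():
    return make_system("sh3_like", 14, seed=42)


@pytest.fixture(scope="session")
def clean_one_site(one_site_system, small_grid, spec_15n):
    return synthesize_fid(one_site_system, small_grid, spec_15n, 0.0)
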