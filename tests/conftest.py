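import numpy as np
import pandas as pd
import pytest

from riverbod import CALIBRATED, DEFAULT_CONSTANTS, Network, Subbasin


@pytest.fixture
def params():
    return CALIBRATED


@pytest.fixture
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture
def chain3():
    """Three-subbasin chain a -> b -> c -> sea, everything at 20 degC."""
    return Network(
        [
            Subbasin(id="a", downstream_id="b", area_km2=4.0, discharge_m3s=1.0,
                     reach_travel_time_days=0.05),
            Subbasin(id="b", downstream_id="c", area_km2=6.0, discharge_m3s=2.0,
                     reach_travel_time_days=0.05),
            Subbasin(id="c", downstream_id="sea", area_km2=8.0, discharge_m3s=3.0,
                     reach_travel_time_days=0.05),
        ]
    )


@pytest.fixture
def zero_emissions_frame():
    def _make(net):
        from riverbod.emissions import DIFFUSE_CATEGORIES, POINT_CATEGORIES, EmissionSet

        ids = pd.Index(net.topo_order, name="id")
        return EmissionSet(
            point=pd.DataFrame(0.0, index=ids, columns=list(POINT_CATEGORIES)),
            diffuse=pd.DataFrame(0.0, index=ids, columns=list(DIFFUSE_CATEGORIES)),
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
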