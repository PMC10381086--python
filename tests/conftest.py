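import numpy as np
import pytest
import xarray as xr

import krillgrowth as kg

EMPIRICAL = ("atkinson2006", "tarling2006", "wiedenmann2008")
MECHANISTIC = ("hofmann2000", "fach2002", "jager2015", "bahlburg2021",
               "ryabov2017")
ALL_MODELS = EMPIRICAL + MECHANISTIC


@pytest.fixture(scope="session")
def models():
    return kg.build_models()


@pytest.fixture(scope="session")
def soi_forcing():
    return kg.synthetic_soi_forcing()


@pytest.fixture(scope="session")
def soi_suite(soi_forcing):
    """Full-suite run on the synthetic South-Orkney season (RK4 default)."""
    return kg.run_suite(soi_forcing)


@pytest.fixture()
def uniform_grid():
    """Tiny 1x3 grid (one latitude) with constant forcing in every cell."""
    doy = np.arange(1, 366)
    lat = np.array([-60.7])
    lon = np.array([-46.0, -45.75, -45.5])
    shape = (len(doy), len(lat), len(lon))
    data = xr.Dataset(
        {
            "sst": (("dayofyear", "lat", "lon"), np.full(shape, 0.5)),
            "chl": (("dayofyear", "lat", "lon"), np.full(shape, 1.0)),
        },
        coords={"dayofyear": doy, "lat": lat, "lon": lon},
    )
    return kg.GridForcing(data=data)
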