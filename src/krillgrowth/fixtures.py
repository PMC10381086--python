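"""Synthetic scenario generator for tests and demonstrations.

Every scenario is fully determined by its (name, overrides, seed) triple
and is generated at run time — nothing is shipped as data. Scenarios:

* ``soi_default`` — the synthetic South-Orkney-like season (1 Nov-15 Apr,
  -1.5 degC / 0.3 mg chl m-3 on 1 Nov, mid-January bloom);
* ``all_ice`` — the same calendar with the ice flag set on every day;
* ``zero_food`` — chlorophyll identically zero;
* ``unlimited_food`` — the SOI series plus model overrides that pin the
  Holling functional response at f = 1 for the DEB family;
* ``toy_grid`` — two years of daily gridded sst/chl NetCDF files with
  hand-computable day-of-year means, for the climatology reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .forcing import SyntheticSOIConfig, synthetic_soi_forcing

SCENARIOS = ("soi_default", "all_ice", "zero_food", "unlimited_food",
             "toy_grid")


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic description of one synthetic test scenario."""

    name: str
    overrides: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; "
                             f"known: {SCENARIOS}")


def _soi(overrides: dict, seed: int) -> pd.DataFrame:
    cfg = SyntheticSOIConfig(**overrides)
    return synthetic_soi_forcing(cfg, seed=seed)


def _toy_grid_files(out_dir: Path, overrides: dict, seed: int) -> dict:
    """Two years of daily 0.05-degree sst/chl with known day-of-year means.

    Each variable is ``base(cell) + signal(doy) +/- year_offset`` with the
    two year offsets cancelling, so the day-of-year climatology equals
    ``base + signal`` exactly and a block mean over 5x5 cells is the mean
    of the bases — both hand-computable in tests.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    n = int(overrides.get("n_cells", 10))
    res = float(overrides.get("resolution", 0.05))
    year_offset = float(overrides.get("year_offset", 0.5))
    lat0 = float(overrides.get("lat0", -61.0))
    lon0 = float(overrides.get("lon0", -45.0))
    lat = lat0 + res * np.arange(n)
    lon = lon0 + res * np.arange(n)
    time = pd.date_range("2013-01-01", "2014-12-31", freq="D")
    doy = time.dayofyear.to_numpy().astype(float)
    offs = np.where(time.year == 2013, -year_offset, year_offset)

    base = (np.arange(n)[:, None] + np.arange(n)[None, :]) * 0.1
    out = {}
    for var, units, amp in (("sst", "degC", 1.0), ("chl", "mg m-3", 0.2)):
        signal = amp * np.sin(2 * np.pi * doy / 365.0)
        cube = (base[None, :, :]
                + signal[:, None, None]
                + offs[:, None, None])
        if var == "chl":
            cube = cube + 1.0  # keep concentrations positive
        da = xr.DataArray(cube, dims=("time", "lat", "lon"),
                          coords={"time": time, "lat": lat, "lon": lon},
                          name=var, attrs={"units": units})
        path = out_dir / f"toy_{var}.nc"
        da.to_dataset().to_netcdf(path, engine="scipy")
        out[var] = path
    return out


def make_fixture(spec: FixtureSpec, out_dir=None):
    """Materialize a scenario.

    Forcing scenarios return a single-location forcing DataFrame (plus,
    for ``unlimited_food``, the model-configuration overrides that pin
    f = 1). ``toy_grid`` writes NetCDF files into ``out_dir`` and returns
    their paths.
    """
    if spec.name == "toy_grid":
        if out_dir is None:
            raise ValueError("toy_grid needs an output directory")
        return _toy_grid_files(Path(out_dir), spec.overrides, spec.seed)

    if spec.name == "soi_default":
        return _soi(spec.overrides, spec.seed)
    if spec.name == "all_ice":
        df = _soi(spec.overrides, spec.seed)
        df["ice"] = True
        return df
    if spec.name == "zero_food":
        ov = {"chl_start": 0.0, "bloom_amplitude": 0.0, **spec.overrides}
        return _soi(ov, spec.seed)
    if spec.name == "unlimited_food":
        forcing = _soi(spec.overrides, spec.seed)
        model_overrides = {"jager2015": {"unlimited_food": True},
                           "bahlburg2021": {"unlimited_food": True}}
        return forcing, model_overrides
    raise AssertionError("unreachable")
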