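"""Environmental forcing: the driver series every growth model consumes.

A single-location forcing series is a pandas DataFrame with one row per
calendar day and the columns

    date         calendar day (datetime64)
    sst          sea-surface temperature, degC
    chl          chlorophyll a concentration, mg m-3
    poc          particulate organic carbon, mg C m-3 (= 50 * chl when derived)
    photoperiod  hours between sunrise and sunset, in [0, 24]
    ice          boolean sea-ice flag
    latitude     degrees (negative south)
    longitude    degrees

Gridded forcing (:class:`GridForcing`) holds day-of-year climatology fields
of sst and chl on a regular lat-lon grid plus a validity mask, and yields
per-cell daily series for a simulation window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

#: mg POC per mg chlorophyll a used to derive the carbon food proxy.
CHL_TO_POC_RATIO = 50.0

FORCING_COLUMNS = ["date", "sst", "chl", "poc", "photoperiod", "ice"]

_SST_UNIT_ALIASES = {"degc", "deg_c", "celsius", "c", "degree_celsius",
                     "degrees_celsius", "°c"}
_CHL_UNIT_ALIASES = {"mg m-3", "mg/m3", "mg m^-3", "mg_m-3", "milligram m-3",
                     "mg chl m-3", "mg m**-3"}


class UnitError(ValueError):
    """Raised on unit-metadata mismatch in climatology input."""


# ---------------------------------------------------------------------------
# photoperiod
# ---------------------------------------------------------------------------

def compute_photoperiod(latitude, day_of_year):
    """Hours between sunrise and sunset (zero-elevation horizon, no twilight).

    Uses the standard solar-declination formula
    ``delta = -23.44 deg * cos(2 pi (N + 10) / 365)`` and the sunrise
    hour-angle ``cos h0 = -tan(phi) tan(delta)``. Inside the polar circles
    the value saturates at 0 (polar night) or 24 (polar day) instead of
    raising. Accepts scalars or arrays; ``day_of_year`` may be fractional.
    """
    lat = np.asarray(latitude, dtype=float)
    doy = np.asarray(day_of_year, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude must be within [-90, 90]")
    decl = np.deg2rad(-23.44 * np.cos(2.0 * np.pi * (doy + 10.0) / 365.0))
    x = -np.tan(np.deg2rad(lat)) * np.tan(decl)
    x = np.clip(x, -1.0, 1.0)
    hours = 24.0 / np.pi * np.arccos(x)
    if hours.ndim == 0:
        return float(hours)
    return hours


# ---------------------------------------------------------------------------
# food proxy and smoothing
# ---------------------------------------------------------------------------

def chl_to_poc(chl, ratio: float = CHL_TO_POC_RATIO):
    """Convert chlorophyll a (mg m-3) to POC (mg C m-3), ``poc = ratio*chl``."""
    arr = np.asarray(chl, dtype=float)
    if np.any(arr < 0):
        raise ValueError("chlorophyll a concentration must be >= 0")
    out = ratio * arr
    if out.ndim == 0:
        return float(out)
    return out


def rolling_mean_smooth(series, window: int = 15):
    """Centered rolling mean ignoring missing values.

    Missing values (NaN) inside a window are excluded: the output is the
    mean of the available observations. A window that contains no
    observations at all yields NaN (flagged missing). The output has the
    same length as the input; a constant series is returned unchanged.
    """
    if window <= 0 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    s = pd.Series(np.asarray(series, dtype=float))
    if len(s) < window:
        raise ValueError("series shorter than smoothing window")
    out = s.rolling(window, center=True, min_periods=1).mean()
    return out.to_numpy()


# ---------------------------------------------------------------------------
# single-location series helpers
# ---------------------------------------------------------------------------

def _validate_forcing(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"forcing series lacks columns {missing}")
    dates = pd.to_datetime(df["date"])
    gaps = dates.diff().dropna()
    if len(gaps) and not (gaps == pd.Timedelta(days=1)).all():
        raise ValueError("forcing series must be contiguous daily, no gaps")
    if (df["chl"] < 0).any():
        raise ValueError("chl must be >= 0")
    if ((df["photoperiod"] < 0) | (df["photoperiod"] > 24)).any():
        raise ValueError("photoperiod must lie in [0, 24]")
    return df


def make_forcing_frame(dates, sst, chl, latitude, longitude=0.0,
                       ice=None, poc=None) -> pd.DataFrame:
    """Assemble a validated single-location forcing DataFrame.

    ``poc`` is derived as ``50 * chl`` unless given; ``photoperiod`` is
    always computed from latitude and day of year.
    """
    dates = pd.to_datetime(pd.Index(dates))
    chl = np.asarray(chl, dtype=float)
    doy = dates.dayofyear.to_numpy().astype(float)
    # fold leap-day observations onto day 59 so the calendar has 365 bins
    doy = np.where(dates.is_leap_year & (doy > 59), doy - 1, doy)
    df = pd.DataFrame(
        {
            "date": dates,
            "sst": np.asarray(sst, dtype=float),
            "chl": chl,
            "poc": chl_to_poc(chl) if poc is None else np.asarray(poc, float),
            "photoperiod": compute_photoperiod(latitude, doy),
            "ice": np.zeros(len(dates), bool) if ice is None else np.asarray(ice, bool),
            "latitude": latitude,
            "longitude": longitude,
        }
    )
    return _validate_forcing(df)


def write_forcing_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, date_format="%Y-%m-%d")


def read_forcing_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    df["ice"] = df["ice"].astype(bool)
    return _validate_forcing(df)


# ---------------------------------------------------------------------------
# synthetic South-Orkney-like seasonal forcing
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSOIConfig:
    """Parameters of the synthetic South-Orkney-like season (1 Nov-15 Apr).

    Chlorophyll is a Gaussian bloom on a baseline, anchored exactly at
    ``chl_start`` on 1 Nov; SST is a seasonal sinusoid anchored exactly at
    ``sst_start`` on 1 Nov. Defaults emulate the satellite climatology of
    the region: -1.5 degC / 0.3 mg m-3 at the start, a mid-January bloom
    peaking near 1.3 mg m-3, declining chlorophyll from late February, and
    an SST maximum of ~0.8 degC in mid-February.
    """

    start: str = "2013-11-01"
    end: str = "2014-04-15"
    latitude: float = -60.7
    longitude: float = -45.0
    chl_start: float = 0.3
    bloom_amplitude: float = 1.0       # mg m-3 above baseline at the peak
    bloom_peak_day: int = 75           # days after 1 Nov (15 January)
    bloom_width_days: float = 25.0     # Gaussian sigma
    sst_start: float = -1.5
    sst_amplitude: float = 1.8         # seasonal half-range, degC
    sst_peak_day: int = 107            # days after 1 Nov (mid-February)
    noise_sd_chl: float = 0.0
    noise_sd_sst: float = 0.0


def synthetic_soi_forcing(config: SyntheticSOIConfig | None = None,
                          seed: int | None = None) -> pd.DataFrame:
    """Generate the 166-day synthetic South-Orkney-like forcing series."""
    cfg = config or SyntheticSOIConfig()
    if cfg.bloom_amplitude < 0 or cfg.sst_amplitude < 0:
        raise ValueError("amplitudes must be non-negative")
    if cfg.noise_sd_chl < 0 or cfg.noise_sd_sst < 0:
        raise ValueError("noise SDs must be non-negative")
    dates = pd.date_range(cfg.start, cfg.end, freq="D")
    t = np.arange(len(dates), dtype=float)

    bump = np.exp(-((t - cfg.bloom_peak_day) ** 2)
                  / (2.0 * cfg.bloom_width_days ** 2))
    baseline = cfg.chl_start - cfg.bloom_amplitude * bump[0]
    chl = baseline + cfg.bloom_amplitude * bump

    phase = 2.0 * np.pi * (t - cfg.sst_peak_day) / 365.0
    mean_sst = cfg.sst_start - cfg.sst_amplitude * np.cos(phase[0])
    sst = mean_sst + cfg.sst_amplitude * np.cos(phase)

    if cfg.noise_sd_chl > 0 or cfg.noise_sd_sst > 0:
        rng = np.random.default_rng(seed)
        chl = chl + rng.normal(0.0, cfg.noise_sd_chl, len(t))
        sst = sst + rng.normal(0.0, cfg.noise_sd_sst, len(t))
    chl = np.clip(chl, 0.0, None)
    return make_forcing_frame(dates, sst, chl, cfg.latitude, cfg.longitude)


# ---------------------------------------------------------------------------
# gridded climatologies
# ---------------------------------------------------------------------------

def _check_units(da: xr.DataArray, variable: str) -> None:
    units = str(da.attrs.get("units", "")).strip().lower()
    if not units:
        raise UnitError(f"variable {variable!r} carries no units attribute")
    if variable == "sst" and units not in _SST_UNIT_ALIASES:
        raise UnitError(f"sst units {units!r} not recognised as degC")
    if variable == "chl" and units not in _CHL_UNIT_ALIASES:
        raise UnitError(f"chl units {units!r} not recognised as mg m-3")


def load_climatology(path, variable: str, resolution: float = 0.25,
                     var_name: str | None = None,
                     min_samples: int = 1) -> xr.Dataset:
    """Build a 365-bin day-of-year climatology from a daily NetCDF file.

    The input must carry ``lat``/``lon``/``time`` coordinates and a daily
    (or finer) time axis. The field is block-mean downsampled to the target
    resolution (which must be an integer multiple of the input spacing),
    then averaged per day of year over the available observations only;
    29 February is folded onto day 59. The returned dataset holds the
    climatology (dims ``dayofyear, lat, lon``), the per-bin sample count
    ``n_samples`` and a boolean ``sparse`` flag marking bins with fewer
    than ``min_samples`` observations (flagged, not dropped).
    """
    ds = xr.open_dataset(path, engine="scipy")
    for coord in ("lat", "lon", "time"):
        if coord not in ds.coords and coord not in ds.dims:
            raise ValueError(f"climatology file lacks coordinate {coord!r}")
    name = var_name or variable
    if name not in ds:
        raise ValueError(f"variable {name!r} not found in {path}")
    da = ds[name]
    _check_units(da, variable)

    spacing = float(abs(np.diff(da["lat"].values).mean()))
    factor = resolution / spacing
    if abs(factor - round(factor)) > 1e-6:
        raise ValueError(
            f"target resolution {resolution} is not an integer multiple of "
            f"the input spacing {spacing}"
        )
    factor = int(round(factor))
    if factor > 1:
        da = da.coarsen(lat=factor, lon=factor, boundary="trim").mean()

    times = pd.DatetimeIndex(da["time"].values)
    doy = times.dayofyear.to_numpy().astype(int)
    doy = np.where(times.is_leap_year & (doy > 59), doy - 1, doy)
    da = da.assign_coords(doy=("time", doy))
    clim = da.groupby("doy").mean("time", skipna=True)
    count = da.notnull().groupby("doy").sum("time")
    out = xr.Dataset(
        {
            variable: clim.rename({"doy": "dayofyear"}),
            "n_samples": count.rename({"doy": "dayofyear"}),
        }
    )
    out["sparse"] = out["n_samples"] < min_samples
    out[variable].attrs["units"] = da.attrs.get("units", "")
    ds.close()
    return out


@dataclass
class GridForcing:
    """Day-of-year climatology forcing on a regular lat-lon grid.

    ``data`` has variables ``sst`` and ``chl`` with dims
    ``(dayofyear, lat, lon)`` and optionally a boolean ``ice`` variable;
    ``mask`` is True for valid (ocean, south-of-Polar-Front) cells and is
    immutable during a run.
    """

    data: xr.Dataset
    mask: xr.DataArray = field(default=None)

    def __post_init__(self):
        for v in ("sst", "chl"):
            if v not in self.data:
                raise ValueError(f"grid forcing lacks variable {v!r}")
        if self.mask is None:
            object.__setattr__(
                self, "mask",
                xr.ones_like(self.data["sst"].isel(dayofyear=0), dtype=bool),
            )

    @property
    def lat(self):
        return self.data["lat"].values

    @property
    def lon(self):
        return self.data["lon"].values

    def cell_series(self, lat: float, lon: float, start, end) -> pd.DataFrame:
        """Daily forcing series for one cell over a simulation window."""
        dates = pd.date_range(start, end, freq="D")
        doy = dates.dayofyear.to_numpy().astype(int)
        doy = np.where(dates.is_leap_year & (doy > 59), doy - 1, doy)
        cell = self.data.sel(lat=lat, lon=lon, method="nearest")
        sst = cell["sst"].sel(dayofyear=doy).values
        chl = cell["chl"].sel(dayofyear=doy).values
        if "ice" in self.data:
            ice = cell["ice"].sel(dayofyear=doy).values.astype(bool)
        else:
            ice = np.zeros(len(dates), bool)
        # cells with missing chl under ice behave as ice-covered days
        missing = ~np.isfinite(chl) | ~np.isfinite(sst)
        ice = ice | missing
        chl = np.where(np.isfinite(chl), chl, 0.0)
        sst = np.where(np.isfinite(sst), sst, 0.0)
        lat_c = float(cell["lat"].values)
        lon_c = float(cell["lon"].values)
        return make_forcing_frame(dates, sst, np.clip(chl, 0, None),
                                  lat_c, lon_c, ice=ice)


def grid_from_climatologies(sst_clim: xr.Dataset, chl_clim: xr.Dataset,
                            ice=None, mask=None) -> GridForcing:
    """Combine sst/chl climatology datasets into a :class:`GridForcing`."""
    data = xr.Dataset({"sst": sst_clim["sst"], "chl": chl_clim["chl"]})
    if ice is not None:
        data["ice"] = ice
    return GridForcing(data=data, mask=mask)
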