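"""Intercomparison analytics.

Response surfaces (daily growth rate over temperature x chlorophyll for a
fixed body length and date), the required-chlorophyll inversion of those
surfaces, per-day ensemble spread of growth trajectories, and per-cell
divergence (coefficient of variation) maps of grid runs.

Conventions: standard deviations are population SDs (divide by the number
of models); the CV denominator is |mean|, with cells whose |mean| falls
below a small threshold flagged as undefined rather than dropped.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .base import GrowthModel

#: default axes covering the circumpolar habitat conditions
DEFAULT_SST_AXIS = np.round(np.arange(-2.0, 4.0 + 1e-9, 0.05), 10)
DEFAULT_CHL_AXIS = np.round(np.arange(0.0, 5.0 + 1e-9, 0.05), 10)

#: reference date of the peak-summer snapshot (15 January)
DEFAULT_DATE = dt.date(2014, 1, 15)

#: |mean| below this (mm) flags an undefined CV
CV_MEAN_THRESHOLD = 0.1


@dataclass
class ResponseSurface:
    """Growth-rate matrix (mm/d) over an sst x chl grid."""

    model_id: str
    length_mm: float
    date: dt.date
    photoperiod: float
    sst_axis: np.ndarray
    chl_axis: np.ndarray
    rates: np.ndarray  # shape (len(sst_axis), len(chl_axis))

    def to_xarray(self) -> xr.DataArray:
        da = xr.DataArray(
            self.rates, dims=("sst", "chl"),
            coords={"sst": self.sst_axis, "chl": self.chl_axis},
            name="growth_rate",
            attrs={"units": "mm d-1", "model": self.model_id,
                   "length_mm": self.length_mm,
                   "photoperiod_h": self.photoperiod,
                   "date": self.date.isoformat()},
        )
        return da

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_netcdf(path, engine="scipy")

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format (sst, chl, growth_rate) table."""
        return (self.to_xarray().to_dataframe().reset_index())

    def max_rate(self) -> float:
        return float(np.nanmax(self.rates))

    def argmax(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.nanargmax(self.rates)),
                                self.rates.shape)
        return float(self.sst_axis[i]), float(self.chl_axis[j])


def response_surface(model: GrowthModel, length_mm: float = 26.0,
                     date: dt.date = DEFAULT_DATE, photoperiod: float = 20.0,
                     sst_axis=None, chl_axis=None) -> ResponseSurface:
    """Daily growth rate of a model at constant (sst, chl) combinations.

    Moult-based models report increment-at-IMP-mean-conditions divided by
    the IMP; under constant forcing the IMP mean equals the point value.
    ``photoperiod`` is an explicit argument (only the photoperiod-DEB
    variant is sensitive to it).
    """
    sst_axis = DEFAULT_SST_AXIS if sst_axis is None else np.asarray(sst_axis, float)
    chl_axis = DEFAULT_CHL_AXIS if chl_axis is None else np.asarray(chl_axis, float)
    for ax, name in ((sst_axis, "sst"), (chl_axis, "chl")):
        if len(ax) < 2 or np.any(np.diff(ax) <= 0):
            raise ValueError(f"{name} axis must be strictly increasing")
    if "photoperiod" in model.requires and photoperiod is None:
        raise ValueError(f"model {model.model_id!r} requires a photoperiod")
    rates = model.daily_rate(length_mm, sst_axis[:, None], chl_axis[None, :],
                             photoperiod=photoperiod, date=date)
    rates = np.broadcast_to(np.asarray(rates, float),
                            (len(sst_axis), len(chl_axis))).copy()
    if not np.all(np.isfinite(rates)):
        raise ValueError("non-finite entries in response surface")
    return ResponseSurface(model_id=model.model_id, length_mm=length_mm,
                           date=date, photoperiod=photoperiod,
                           sst_axis=sst_axis, chl_axis=chl_axis, rates=rates)


def required_chl(model: GrowthModel, target_rate: float, sst: float,
                 length_mm: float = 26.0, photoperiod: float = 20.0,
                 date: dt.date = DEFAULT_DATE, chl_max: float = 20.0,
                 tol: float = 1e-3):
    """Smallest chlorophyll achieving a target growth rate, or "unreachable".

    Bisection on [0, chl_max] to ``tol`` (mg m-3). The model response must
    be monotone non-decreasing in chlorophyll (checked on a scan; a
    violation raises). If even saturating food cannot reach the target
    (e.g. the capped budgets for targets above the cap), returns the
    string ``"unreachable"``.
    """
    def rate(chl):
        return float(model.daily_rate(length_mm, sst, chl,
                                      photoperiod=photoperiod, date=date))

    scan = np.linspace(0.0, chl_max, 201)
    vals = np.array([rate(c) for c in scan])
    if np.any(np.diff(vals) < -1e-9):
        raise ValueError(f"model {model.model_id!r} response is not "
                         "monotone in chlorophyll")
    if vals[-1] < target_rate:
        return "unreachable"
    if vals[0] >= target_rate:
        return 0.0
    lo, hi = 0.0, chl_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if rate(mid) >= target_rate:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def ensemble_spread(trajectories: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-day mean and population SD of length across models."""
    if len(trajectories) < 2:
        raise ValueError("ensemble spread needs at least two models")
    frames = []
    ref_dates = None
    for mid, df in trajectories.items():
        dates = pd.to_datetime(df["date"]).reset_index(drop=True)
        if ref_dates is None:
            ref_dates = dates
        elif not dates.equals(ref_dates):
            raise ValueError("trajectories have misaligned dates")
        frames.append(df["length_mm"].to_numpy(float))
    lengths = np.stack(frames)  # (models, days)
    return pd.DataFrame({
        "date": ref_dates,
        "mean_mm": lengths.mean(axis=0),
        "sd_mm": lengths.std(axis=0, ddof=0),
    })


@dataclass
class DivergenceMap:
    """Per-cell cross-model mean, SD and coefficient of variation."""

    data: xr.Dataset  # variables: mean, sd, cv, cv_undefined

    def to_netcdf(self, path) -> None:
        self.data.to_netcdf(path, engine="scipy")


def divergence_map(final_fields: xr.Dataset | dict,
                   mean_threshold: float = CV_MEAN_THRESHOLD) -> DivergenceMap:
    """Cross-model divergence of per-cell final values.

    ``final_fields`` maps model id -> 2-D (lat, lon) field of final
    lengths (or any aligned per-cell quantity). CV = SD/|mean|; cells with
    |mean| below ``mean_threshold`` are flagged ``cv_undefined`` (CV set
    to NaN there), never silently dropped.
    """
    if isinstance(final_fields, xr.Dataset):
        fields = {v: final_fields[v] for v in final_fields.data_vars}
    else:
        fields = dict(final_fields)
    if len(fields) < 2:
        raise ValueError("divergence map needs at least two models")
    ref = None
    arrays = []
    for mid, da in fields.items():
        da = xr.DataArray(da) if not isinstance(da, xr.DataArray) else da
        if ref is None:
            ref = da
        elif da.shape != ref.shape:
            raise ValueError("model fields are not aligned")
        arrays.append(np.asarray(da, float))
    stack = np.stack(arrays)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    undefined = np.abs(mean) < mean_threshold
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(undefined, np.nan, sd / np.abs(mean))
    coords = ref.coords if ref is not None else None
    ds = xr.Dataset(
        {
            "mean": (ref.dims, mean),
            "sd": (ref.dims, sd),
            "cv": (ref.dims, cv),
            "cv_undefined": (ref.dims, undefined),
        },
        coords=coords,
    )
    return DivergenceMap(data=ds)
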