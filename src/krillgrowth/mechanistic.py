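"""Mechanistic (energy-budget) krill growth models.

Five models sharing the :class:`~krillgrowth.base.GrowthModel` contract:

* **Hofmann/Lascara-type** and **Fach-type**: POC-driven bioenergetic
  budgets. Saturating ingestion scales with carbon mass^(2/3), respiration
  with mass^0.85 and a Q10 temperature correction; the net carbon balance
  maps to a length change through the mass-length coupling and is capped
  at +0.25 mm/d. The Fach variant differs only in a weaker respiration Q10
  (a registry entry, not a code branch). Heterotrophic and ice-algal food
  inputs are fixed to zero; POC derives from chlorophyll at 50:1.
* **Simplified DEB** (Jager/Ravagnan-type) and **photoperiod DEB**
  (Bahlburg-type): DEBkiss budgets in which assimilation scales with
  volumetric length^2 and maintenance with volumetric length^3. That
  allometry reduces, in physical length, to a von-Bertalanffy equation
  ``dL/dt = rB(T) (f L_inf - L)`` with asymptote ~60 mm at f = 1, where f
  is a Holling type II functional response of chlorophyll (the original
  simplified model assumed unlimited food, f = 1; the ``unlimited_food``
  flag restores that assumption). The photoperiod variant multiplies both
  ingestion and maintenance by a bounded day-length scaling, lowering the
  energetic cost of the dark season.
* **Ryabov-type** energy partitioning: Holling II uptake with a lower
  half-saturation (in-situ calibration data), metabolism charged first and
  the residual allocated to somatic growth, plus a winter metabolic
  switch.

Temperature enters the DEB-family rates through an Arrhenius correction
and the Hofmann/Fach respiration through Q10.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .base import register_model
from .empirical import ContinuousGrowthModel
from .forcing import CHL_TO_POC_RATIO
from .params import ParameterSet, get_parameters


# ---------------------------------------------------------------------------
# shared pieces
# ---------------------------------------------------------------------------

def holling_type_II(chl, half_saturation):
    """Scaled functional response ``f = chl / (chl + K)`` in [0, 1)."""
    if np.any(np.asarray(half_saturation, float) <= 0):
        raise ValueError("half-saturation must be positive")
    F = np.asarray(chl, float)
    if np.any(F < 0):
        raise ValueError("chl must be >= 0")
    out = F / (F + half_saturation)
    return float(out) if out.ndim == 0 else out


def _parse_mmdd(s: str) -> tuple[int, int]:
    m, d = s.split("-")
    return int(m), int(d)


@dataclass(frozen=True)
class MetabolicModifiers:
    """Winter metabolic switch and optional photoperiod scaling.

    ``factor`` multiplies metabolic terms inside the calendar window
    [start, end] (MM-DD, inclusive; may wrap the year end) and is 1
    outside it. ``photoperiod_scaling`` is a bounded function of day
    length in [0, 24], monotone increasing (photoperiod-DEB only).
    """

    factor: float = 1.0
    window_start: str | None = None
    window_end: str | None = None
    photoperiod_scaling: Callable | None = None

    def __post_init__(self):
        if not (0.0 < self.factor <= 1.0):
            raise ValueError("winter factor must lie in (0, 1]")
        if (self.window_start is None) != (self.window_end is None):
            raise ValueError("winter window needs both start and end")
        if self.window_start is not None and \
                _parse_mmdd(self.window_start) == _parse_mmdd(self.window_end):
            raise ValueError("degenerate (inverted) winter window")


def winter_switch(date: dt.date, modifiers: MetabolicModifiers) -> float:
    """Metabolic factor for a calendar day: <1 inside the winter window."""
    if modifiers.window_start is None:
        return 1.0
    start = _parse_mmdd(modifiers.window_start)
    end = _parse_mmdd(modifiers.window_end)
    key = (date.month, date.day)
    if start <= end:
        inside = start <= key <= end
    else:  # window wraps the year end
        inside = key >= start or key <= end
    return modifiers.factor if inside else 1.0


def _modifiers_from(params: ParameterSet) -> MetabolicModifiers:
    if "winter_factor" in params.coefficients:
        return MetabolicModifiers(factor=params["winter_factor"],
                                  window_start=params["winter_start"],
                                  window_end=params["winter_end"])
    return MetabolicModifiers()


# ---------------------------------------------------------------------------
# Hofmann / Fach bioenergetic budget
# ---------------------------------------------------------------------------

class _CarbonBudgetModel(ContinuousGrowthModel):
    """POC-driven carbon budget with a hard cap on daily length change."""

    requires = frozenset({"sst", "chl", "poc"})

    def __init__(self):
        self.params = get_parameters(self.model_id, "all krill")
        self.modifiers = _modifiers_from(self.params)

    @property
    def metadata(self):
        return self.params.calibration

    def carbon_mass(self, length_mm):
        """Body carbon (mg C) from physical length (mm)."""
        p = self.params
        return p["mass_coeff"] * np.asarray(length_mm, float) ** p["mass_exp"]

    def uncapped_rate(self, length_mm, sst, chl, date=None):
        p = self.params
        L = np.asarray(length_mm, float)
        T = np.asarray(sst, float)
        poc = CHL_TO_POC_RATIO * np.asarray(chl, float)
        W = self.carbon_mass(L)
        # Ivlev saturation of ingestion on the carbon food proxy
        phi = 1.0 - np.exp(-poc / p["ingest_half_sat_poc"])
        assim = p["assimilation_eff"] * p["ingest_max"] * W ** (2.0 / 3.0) * phi
        wf = winter_switch(date, self.modifiers) if date is not None else 1.0
        resp = (p["resp_coeff"] * W ** p["resp_exp"]
                * p["resp_q10"] ** (T / 10.0) * wf)
        dW_dL = p["mass_coeff"] * p["mass_exp"] * L ** (p["mass_exp"] - 1.0)
        return (assim - resp) / dW_dL

    def daily_rate(self, length_mm, sst, chl, photoperiod=12.0, date=None):
        out = np.minimum(self.uncapped_rate(length_mm, sst, chl, date),
                         self.params["growth_cap"])
        if not np.all(np.isfinite(out)):
            raise ValueError("non-finite state in carbon-budget rate")
        return float(out) if np.ndim(out) == 0 else out


@register_model
class HofmannModel(_CarbonBudgetModel):
    model_id = "hofmann2000"
    label = "Hofmann & Lascara (2000)"


@register_model
class FachModel(_CarbonBudgetModel):
    model_id = "fach2002"
    label = "Fach et al. (2002)"


def hofmann_fach_step(state, env, model: _CarbonBudgetModel,
                      env_mid=None, env_next=None, integrator="euler"):
    """One day of the Hofmann/Fach budget (thin functional wrapper)."""
    return model.step(state, env, env_mid, env_next, integrator)


# ---------------------------------------------------------------------------
# DEB family
# ---------------------------------------------------------------------------

class _DEBModel(ContinuousGrowthModel):
    """DEBkiss budget in von-Bertalanffy reduction (physical length)."""

    variant = "simplified"

    def __init__(self, unlimited_food: bool = False):
        self.params = get_parameters(self.model_id, "all krill")
        self.unlimited_food = unlimited_food

    @property
    def metadata(self):
        return self.params.calibration

    def _arrhenius(self, sst):
        p = self.params
        T_kelvin = 273.15 + np.asarray(sst, float)
        return np.exp(p["arrhenius_temp"] / p["temp_ref"]
                      - p["arrhenius_temp"] / T_kelvin)

    def _activity(self, photoperiod):
        return 1.0

    def functional_response(self, chl):
        if self.unlimited_food:
            return np.ones_like(np.asarray(chl, float))
        return holling_type_II(chl, self.params["food_half_sat"])

    def respiration(self, length_mm, sst, photoperiod=12.0):
        """Maintenance flux surrogate (d-1 * mm): rB(T) * activity * L."""
        p = self.params
        return (p["von_bert_rate"] * self._arrhenius(sst)
                * self._activity(photoperiod) * np.asarray(length_mm, float))

    def daily_rate(self, length_mm, sst, chl, photoperiod=12.0, date=None):
        p = self.params
        f = self.functional_response(chl)
        rate = (p["von_bert_rate"] * self._arrhenius(sst)
                * self._activity(photoperiod)
                * (f * p["length_inf"] - np.asarray(length_mm, float)))
        out = np.asarray(rate)
        if not np.all(np.isfinite(out)):
            raise ValueError("non-finite state in DEB rate")
        return float(out) if out.ndim == 0 else out


@register_model
class SimplifiedDEBModel(_DEBModel):
    """Jager/Ravagnan-type simplified DEB, food-scaled via the borrowed
    Holling II parameterization (``unlimited_food=True`` restores the
    original assumption)."""

    model_id = "jager2015"
    label = "Jager & Ravagnan (2015)"
    variant = "simplified"
    requires = frozenset({"sst", "chl"})


@register_model
class PhotoperiodDEBModel(_DEBModel):
    """Bahlburg-type DEB with day-length scaling of ingestion and
    respiration (bounded, monotone in day length over [0, 24])."""

    model_id = "bahlburg2021"
    label = "Bahlburg et al. (2021)"
    variant = "photoperiod"
    requires = frozenset({"sst", "chl", "photoperiod"})

    def _activity(self, photoperiod):
        p = self.params
        P = np.clip(np.asarray(photoperiod, float), 0.0, 24.0)
        return p["photo_floor"] + p["photo_slope"] * P / 24.0


def deb_step(state, env, model: _DEBModel, env_mid=None, env_next=None,
             integrator="euler"):
    """One day of a DEB-family model (thin functional wrapper)."""
    return model.step(state, env, env_mid, env_next, integrator)


# ---------------------------------------------------------------------------
# Ryabov energy partitioning
# ---------------------------------------------------------------------------

@register_model
class RyabovModel(ContinuousGrowthModel):
    """Energy-partitioning model: Holling II uptake (low half-saturation),
    metabolism first, residual to somatic growth; winter metabolic switch."""

    model_id = "ryabov2017"
    label = "Ryabov et al. (2017)"
    requires = frozenset({"sst", "chl"})

    def __init__(self):
        self.params = get_parameters("ryabov2017", "all krill")
        self.modifiers = _modifiers_from(self.params)

    @property
    def metadata(self):
        return self.params.calibration

    def _arrhenius(self, sst):
        p = self.params
        T_kelvin = 273.15 + np.asarray(sst, float)
        return np.exp(p["arrhenius_temp"] / p["temp_ref"]
                      - p["arrhenius_temp"] / T_kelvin)

    def daily_rate(self, length_mm, sst, chl, photoperiod=12.0, date=None):
        p = self.params
        f = holling_type_II(chl, p["food_half_sat"])
        wf = winter_switch(date, self.modifiers) if date is not None else 1.0
        rate = (wf * p["growth_rate"] * self._arrhenius(sst)
                * (f * p["length_inf"] - np.asarray(length_mm, float)))
        out = np.asarray(rate)
        if not np.all(np.isfinite(out)):
            raise ValueError("non-finite state in energy-partitioning rate")
        return float(out) if out.ndim == 0 else out


def ryabov_step(state, env, model: RyabovModel, env_mid=None, env_next=None,
                integrator="euler"):
    """One day of the energy-partitioning model (thin functional wrapper)."""
    return model.step(state, env, env_mid, env_next, integrator)
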