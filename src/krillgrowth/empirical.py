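"""Empirical krill growth machinery.

Three building blocks from the observational literature:

* the instantaneous daily-growth-rate (DGR) function of Atkinson-type:
  additive terms quadratic in body length, quadratic in temperature and
  saturating (Michaelis-Menten) in chlorophyll a, with stage-specific
  parameterizations (juvenile / adult female / all krill);
* a per-moult growth-increment function derived from the same fits
  (DGR scaled by the reference intermoult period of the calibration data
  and proportional to body length);
* two intermoult-period (IMP) functions: the temperature-only exponential
  decay (Kawaguchi-type) and the temperature x length x stage model
  (Tarling-type, hyperbolic in temperature).

They combine into three models of the suite: the pure-rate Atkinson model
(length changes every day) and two moult-based composites in which krill
keep a constant length until they moult (Wiedenmann-type: Kawaguchi IMPs;
Tarling-composite: Tarling IMPs). In the composites the growth increment
at moulting is evaluated at the mean temperature and chlorophyll over the
elapsed intermoult period, and sea-ice days extend the IMP by one day each.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import replace

import numpy as np

from .base import (GrowthModel, KrillState, MoultClock, register_model)
from .params import ParameterSet, get_parameters

#: body length (mm) at which the stage parameterization switches
STAGE_SWITCH_MM = 35.0


# ---------------------------------------------------------------------------
# core empirical functions
# ---------------------------------------------------------------------------

def atkinson_dgr(length, sst, chl, params: ParameterSet):
    """Instantaneous daily growth rate (mm/d), Atkinson-type.

    ``dgr = a + b L + c L^2 + d F/(e + F) + f T + g T^2`` with F the
    chlorophyll a concentration. May be negative; strictly non-decreasing
    in chlorophyll. Vectorized over all inputs.
    """
    L = np.asarray(length, float)
    T = np.asarray(sst, float)
    F = np.asarray(chl, float)
    if np.any(F < 0):
        raise ValueError("chl must be >= 0")
    out = (params["dgr_intercept"]
           + params["dgr_length"] * L
           + params["dgr_length_sq"] * L ** 2
           + params["dgr_food_max"] * F / (params["dgr_food_half_sat"] + F)
           + params["dgr_temp"] * T
           + params["dgr_temp_sq"] * T ** 2)
    return float(out) if out.ndim == 0 else out


def atkinson_increment(length, sst, chl, params: ParameterSet):
    """Growth increment at moulting (mm per moult), Atkinson-type.

    The per-moult increment model expresses the observed moult jump as a
    fraction of body length; it equals the DGR fit scaled by the reference
    IMP of the calibration data and proportional to body length relative
    to the calibration reference length.
    """
    L = np.asarray(length, float)
    scale = params["imp_ref_days"] * L / params["length_ref_mm"]
    out = atkinson_dgr(length, sst, chl, params) * scale
    return float(out) if np.ndim(out) == 0 else out


def kawaguchi_imp(sst, params: ParameterSet | None = None):
    """Temperature-only intermoult period (days): exponential decay.

    ``IMP = a exp(-b T)``; 30 days at 0 degC, monotonically decreasing in
    temperature. Outside the calibration temperature window the curve is
    extrapolated as-is (the registry records the window; no clamping).
    """
    p = params or get_parameters("kawaguchi2006", "all krill")
    T = np.asarray(sst, float)
    out = p["imp_at_zero"] * np.exp(-p["imp_decay"] * T)
    return float(out) if out.ndim == 0 else out


def tarling_imp(sst, length, params: ParameterSet):
    """Temperature x length x stage intermoult period (days).

    Adult females: ``IMP = s (L/L_ref) / (1 + a T + b T^2)`` — the moult
    rate is a downward parabola peaking at 0.5 degC, so the IMP is
    hyperbolic in temperature, shortest near 0.5 degC and lengthening
    above it; 10 days at (0 degC, 35 mm). Juveniles: nearly
    length-independent with an interior IMP maximum at 3 degC.
    """
    T = np.asarray(sst, float)
    L = np.asarray(length, float)
    if np.any(L <= 0):
        raise ValueError("length must be positive")
    if params.stage == "adult female":
        rate = 1.0 + params["rate_temp_lin"] * T + params["rate_temp_sq"] * T ** 2
        if np.any(rate <= 0):
            raise ValueError("Tarling adult-female IMP undefined: moult rate "
                             "non-positive at this temperature")
        out = params["imp_scale"] * (L / params["length_ref_mm"]) / rate
    elif params.stage == "juvenile":
        out = params["imp_scale"] * (
            1.0 - params["temp_curvature"] * (T - params["temp_optimum"]) ** 2
        )
        if np.any(np.asarray(out) <= 0):
            raise ValueError("Tarling juvenile IMP non-positive at this "
                             "temperature")
        out = out + 0.0 * L  # broadcast against length
    else:
        raise ValueError(f"unsupported stage for Tarling IMP: {params.stage!r}")
    return float(out) if np.ndim(out) == 0 else out


def stage_select(length_mm: float, model_id: str) -> str:
    """Stage parameterization used at a given body length.

    Below 35 mm every model runs its juvenile parameterization; at and
    above 35 mm the Atkinson-family models use "all krill" while the
    Tarling composite uses "adult female" (no all-krill Tarling IMP fit
    exists).
    """
    if length_mm <= 0:
        raise ValueError("length must be positive")
    if length_mm < STAGE_SWITCH_MM:
        return "juvenile"
    if model_id in ("tarling2006", "tarling_composite"):
        return "adult female"
    return "all krill"


# ---------------------------------------------------------------------------
# generic moult step
# ---------------------------------------------------------------------------

def _round_imp(imp: float) -> int:
    return max(1, int(round(float(imp))))


def moult_step(state: KrillState, env, imp_fn, increment_fn,
               stage_fn=None) -> KrillState:
    """Advance a moult-based model by one day.

    * ice day: the IMP is extended by one day; no growth, no environmental
      accumulation;
    * non-moult day: length unchanged, clock advanced, running means of
      sst and chl updated;
    * moult day: length changes by ``increment_fn(length, mean_sst,
      mean_chl, stage)`` evaluated over the elapsed IMP, the stage is
      re-evaluated, and a fresh IMP is drawn from ``imp_fn(sst, length,
      stage)`` at the current day's conditions.

    Negative increments are applied as shrinkage (no floor).
    """
    clock: MoultClock = state.extras["clock"]
    if state.date != env.date:
        raise ValueError(f"clock/forcing date mismatch: state at {state.date}, "
                         f"forcing at {env.date}")
    clock = replace(clock)
    new_length = state.length_mm
    new_stage = state.stage
    moulted = False
    if env.ice:
        clock.ice_extension += 1
    else:
        clock.elapsed += 1
        clock.sum_sst += env.sst
        clock.sum_chl += env.chl
        clock.n_env += 1
        clock.check()
        # ice days do not count toward the elapsed IMP, so each one
        # lengthens the calendar span of the moult cycle by one day
        if clock.elapsed >= clock.duration_days:
            inc = increment_fn(state.length_mm, clock.mean_sst,
                               clock.mean_chl, state.stage)
            new_length = max(state.length_mm + inc, 1e-3)
            moulted = True
            if stage_fn is not None:
                new_stage = stage_fn(new_length)
            clock = MoultClock(
                duration_days=_round_imp(imp_fn(env.sst, new_length, new_stage))
            )
    return KrillState(
        length_mm=new_length,
        date=state.date + dt.timedelta(days=1),
        stage=new_stage,
        extras={**state.extras, "clock": clock, "moulted": moulted,
                "imp_days": clock.duration_days},
    )


# ---------------------------------------------------------------------------
# continuous-rate base (shared with the mechanistic module)
# ---------------------------------------------------------------------------

class ContinuousGrowthModel(GrowthModel):
    """Model whose state is length only and which defines a daily rate."""

    continuous = True

    def initial_state(self, length_mm, date, env_row=None) -> KrillState:
        return KrillState(length_mm=length_mm, date=date,
                          stage=stage_select(length_mm, self.model_id))

    def step(self, state, env_row, env_mid=None, env_next=None,
             integrator="euler"):
        if env_row.ice:
            return KrillState(state.length_mm,
                              state.date + dt.timedelta(days=1), state.stage)
        L = state.length_mm
        if integrator == "euler" or env_mid is None or env_next is None:
            new_L = L + self._rate_env(L, env_row)
        elif integrator == "rk4":
            k1 = self._rate_env(L, env_row)
            k2 = self._rate_env(L + 0.5 * k1, env_mid)
            k3 = self._rate_env(L + 0.5 * k2, env_mid)
            k4 = self._rate_env(L + k3, env_next)
            new_L = L + (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        else:
            raise ValueError(f"unknown integrator {integrator!r}")
        new_L = max(new_L, 1e-3)
        return KrillState(new_L, state.date + dt.timedelta(days=1),
                          stage=stage_select(new_L, self.model_id))

    def _rate_env(self, length, env):
        return float(self.daily_rate(length, env.sst, env.chl,
                                     env.photoperiod, date=env.date))


# ---------------------------------------------------------------------------
# the three empirical models
# ---------------------------------------------------------------------------

@register_model
class AtkinsonModel(ContinuousGrowthModel):
    """Pure-rate empirical model: the DGR applies every day.

    The stage parameterization (juvenile below 35 mm, all-krill above) is
    re-evaluated daily because the length changes daily.
    """

    model_id = "atkinson2006"
    label = "Atkinson et al. (2006)*"
    is_empirical = True
    requires = frozenset({"sst", "chl"})

    def __init__(self):
        self._params = {s: get_parameters("atkinson2006", s)
                        for s in ("juvenile", "all krill")}

    @property
    def metadata(self):
        return self._params["all krill"].calibration

    def daily_rate(self, length_mm, sst, chl, photoperiod=12.0, date=None):
        L = np.asarray(length_mm, float)
        juv = atkinson_dgr(L, sst, chl, self._params["juvenile"])
        adult = atkinson_dgr(L, sst, chl, self._params["all krill"])
        out = np.where(L < STAGE_SWITCH_MM, juv, adult)
        return float(out) if out.ndim == 0 else out


class _MoultCompositeModel(GrowthModel):
    """Shared machinery of the two moult-based composites."""

    is_empirical = True
    continuous = False
    requires = frozenset({"sst", "chl"})

    def _increment_params(self, stage: str) -> ParameterSet:
        return get_parameters("atkinson2006", stage)

    def _imp(self, sst, length, stage):  # pragma: no cover - abstract
        raise NotImplementedError

    def _increment(self, length, sst, chl, stage):
        return atkinson_increment(length, sst, chl,
                                  self._increment_params(stage))

    def initial_state(self, length_mm, date, env_row=None) -> KrillState:
        stage = stage_select(length_mm, self.model_id)
        if env_row is not None:
            imp = self._imp(env_row.sst, length_mm, stage)
        else:
            imp = self._imp(0.0, length_mm, stage)
        return KrillState(
            length_mm=length_mm, date=date, stage=stage,
            extras={"clock": MoultClock(duration_days=_round_imp(imp)),
                    "moulted": False, "imp_days": _round_imp(imp)},
        )

    def step(self, state, env_row, env_mid=None, env_next=None,
             integrator="euler"):
        # moulting is a discrete daily event; the integrator choice does
        # not apply
        return moult_step(
            state, env_row,
            imp_fn=self._imp,
            increment_fn=self._increment,
            stage_fn=lambda L: stage_select(L, self.model_id),
        )

    def daily_rate(self, length_mm, sst, chl, photoperiod=12.0, date=None):
        """Increment at IMP-mean conditions divided by the IMP. Under the
        constant forcing of a response surface the IMP mean equals the
        point value."""
        if np.ndim(length_mm) != 0:
            raise ValueError("moult-based rates take a scalar body length")
        stage = stage_select(float(length_mm), self.model_id)
        inc = atkinson_increment(length_mm, sst, chl,
                                 self._increment_params(stage))
        imp = self._imp(sst, float(length_mm), stage)
        out = np.asarray(inc) / np.asarray(imp)
        return float(out) if out.ndim == 0 else out


@register_model
class WiedenmannModel(_MoultCompositeModel):
    """Moult-based composite: Atkinson increments + Kawaguchi (temperature-
    only) intermoult periods. Below 35 mm the juvenile increment
    parameterization applies, above it the all-krill one."""

    model_id = "wiedenmann2008"
    label = "Wiedenmann et al. (2008)*"

    def __init__(self):
        self._kawaguchi = get_parameters("kawaguchi2006", "all krill")

    @property
    def metadata(self):
        return self._kawaguchi.calibration

    def _imp(self, sst, length, stage):
        return kawaguchi_imp(sst, self._kawaguchi)


@register_model
class TarlingCompositeModel(_MoultCompositeModel):
    """Moult-based composite: Atkinson increments + Tarling (temperature x
    length x stage) intermoult periods; adult-female parameterizations
    above the 35 mm switch."""

    model_id = "tarling2006"
    label = "Tarling et al. (2006)*"

    def __init__(self):
        self._imp_params = {s: get_parameters("tarling2006", s)
                            for s in ("juvenile", "adult female")}

    @property
    def metadata(self):
        return self._imp_params["juvenile"].calibration

    def _imp(self, sst, length, stage):
        return tarling_imp(sst, length, self._imp_params[stage])

    def _increment_params(self, stage):
        return get_parameters("atkinson2006", stage)
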