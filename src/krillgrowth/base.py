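"""Common growth-model contract shared by every implemented krill model.

Every model — empirical or mechanistic — implements the same surface:

* :meth:`GrowthModel.initial_state` builds a :class:`KrillState` for a
  given start length and date (first intermoult period, steady-state
  reserves, ... as each model defines);
* :meth:`GrowthModel.step` advances the state by exactly one day given the
  forcing for that day;
* :meth:`GrowthModel.daily_rate` evaluates the model's daily growth rate
  (mm/d) under constant forcing, which is what response surfaces and
  required-chlorophyll inversions consume. For moult-based models this is
  increment-at-moult divided by the intermoult period.

``requires`` declares the forcing columns a model needs so the engine can
fail loudly on model/forcing mismatch.
"""

from __future__ import annotations

import datetime as dt
from abc import ABC, abstractmethod
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np


@dataclass
class KrillState:
    """Simulated individual: physical length plus model-specific extras."""

    length_mm: float
    date: dt.date
    stage: str = "juvenile"
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.length_mm) or self.length_mm <= 0:
            raise ValueError(f"physical length must be positive and finite, "
                             f"got {self.length_mm}")


@dataclass
class MoultClock:
    """Intermoult bookkeeping for moult-based models.

    ``duration_days`` is the current IMP; ice-covered days extend it by one
    day each (``ice_extension``); the running environmental means cover
    exactly the elapsed non-ice days.
    """

    duration_days: int
    elapsed: int = 0
    sum_sst: float = 0.0
    sum_chl: float = 0.0
    n_env: int = 0
    ice_extension: int = 0

    @property
    def mean_sst(self) -> float:
        return self.sum_sst / self.n_env if self.n_env else 0.0

    @property
    def mean_chl(self) -> float:
        return self.sum_chl / self.n_env if self.n_env else 0.0

    def check(self) -> None:
        if self.elapsed > self.duration_days + self.ice_extension:
            raise RuntimeError("moult clock overran its intermoult period")


class GrowthModel(ABC):
    """Uniform interface implemented by all eight krill growth models."""

    model_id: str = ""
    label: str = ""
    is_empirical: bool = False
    #: forcing columns the model consumes
    requires: frozenset = frozenset({"sst", "chl"})
    #: continuous-rate models integrate with euler/rk4; moult-based models
    #: advance by discrete daily events and ignore the integrator choice
    continuous: bool = True

    @property
    def metadata(self) -> dict:
        """Calibration metadata of the primary parameter set."""
        return {}

    @abstractmethod
    def initial_state(self, length_mm: float, date: dt.date,
                      env_row=None) -> KrillState:
        ...

    @abstractmethod
    def step(self, state: KrillState, env_row, env_mid=None, env_next=None,
             integrator: str = "euler") -> KrillState:
        """Advance one day. ``env_mid``/``env_next`` carry interpolated
        forcing for the RK4 stages; ice handling happens inside."""

    @abstractmethod
    def daily_rate(self, length_mm, sst, chl, photoperiod=12.0,
                   date: dt.date | None = None):
        """Daily growth rate (mm/d) under constant forcing; vectorized."""


def advance_date(state: KrillState, new_length: float) -> KrillState:
    return replace(state, length_mm=new_length,
                   date=state.date + dt.timedelta(days=1))


MODEL_CLASSES: dict[str, type] = {}


def register_model(cls):
    """Class decorator adding a model to the suite registry."""
    MODEL_CLASSES[cls.model_id] = cls
    return cls


def build_models(ids=None, **overrides) -> dict[str, GrowthModel]:
    """Instantiate the suite (or a subset) with default configuration."""
    ids = list(MODEL_CLASSES) if ids is None else list(ids)
    out = {}
    for mid in ids:
        if mid not in MODEL_CLASSES:
            raise KeyError(f"unknown model id {mid!r}; "
                           f"known: {sorted(MODEL_CLASSES)}")
        out[mid] = MODEL_CLASSES[mid](**overrides.get(mid, {}))
    return out
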