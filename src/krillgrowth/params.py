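"""Citation-tagged model parameter registry.

Every coefficient used by a growth model lives in a YAML registry file
shipped with the package (``krillgrowth/registry``), together with its
units and a citation of the original model publication. Loading fails
loudly on entries without a citation, so no "anonymous" constant can enter
a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import yaml

STAGE_LABELS = ("juvenile", "adult female", "adult male", "all krill")


class RegistryError(ValueError):
    """Raised when a registry file is malformed or incomplete."""


@dataclass(frozen=True)
class ParameterSet:
    """Named coefficient collection for one model/stage.

    Attributes
    ----------
    model_id : str
        Registry identifier of the model (e.g. ``"atkinson2006"``).
    stage : str
        One of :data:`STAGE_LABELS`.
    coefficients : dict
        Mapping coefficient name -> numeric value (or string for calendar
        entries such as winter-window bounds).
    units : dict
        Mapping coefficient name -> unit string.
    citations : dict
        Mapping coefficient name -> citation string (always present).
    source : str
        Citation of the original publication of the model/stage fit.
    calibration : dict
        Calibration metadata (region, season, food proxy, chl-range
        descriptor, temperature range).
    """

    model_id: str
    stage: str
    coefficients: dict[str, Any]
    units: dict[str, str]
    citations: dict[str, str]
    source: str
    calibration: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Any:
        try:
            return self.coefficients[name]
        except KeyError:
            raise RegistryError(
                f"model {self.model_id!r} stage {self.stage!r} has no "
                f"coefficient {name!r}"
            ) from None


def _parse(doc: dict, origin: str) -> ParameterSet:
    for key in ("model", "stage", "source", "coefficients"):
        if key not in doc:
            raise RegistryError(f"{origin}: missing top-level field {key!r}")
    stage = doc["stage"]
    if stage not in STAGE_LABELS:
        raise RegistryError(
            f"{origin}: stage {stage!r} not in {STAGE_LABELS}"
        )
    coeffs, units, citations = {}, {}, {}
    for name, entry in doc["coefficients"].items():
        if not isinstance(entry, dict) or "value" not in entry:
            raise RegistryError(f"{origin}: coefficient {name!r} has no value")
        if not entry.get("citation"):
            raise RegistryError(f"{origin}: coefficient {name!r} has no citation")
        coeffs[name] = entry["value"]
        units[name] = entry.get("units", "")
        citations[name] = entry["citation"]
    return ParameterSet(
        model_id=doc["model"],
        stage=stage,
        coefficients=coeffs,
        units=units,
        citations=citations,
        source=doc["source"],
        calibration=doc.get("calibration", {}),
    )


def load_parameter_file(path) -> ParameterSet:
    """Load a single registry YAML file from an explicit path."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse(doc, str(path))


def _registry_files():
    root = resources.files("krillgrowth") / "registry"
    return sorted(p for p in root.iterdir() if p.name.endswith(".yaml"))


def load_registry() -> dict[tuple[str, str], ParameterSet]:
    """Load every packaged registry file, keyed by (model_id, stage)."""
    registry: dict[tuple[str, str], ParameterSet] = {}
    for path in _registry_files():
        doc = yaml.safe_load(path.read_text())
        ps = _parse(doc, path.name)
        key = (ps.model_id, ps.stage)
        if key in registry:
            raise RegistryError(f"duplicate registry entry for {key}")
        registry[key] = ps
    return registry


_CACHE: dict[tuple[str, str], ParameterSet] | None = None


def get_parameters(model_id: str, stage: str = "all krill") -> ParameterSet:
    """Return the packaged :class:`ParameterSet` for a model/stage."""
    global _CACHE
    if _CACHE is None:
        _CACHE = load_registry()
    try:
        return _CACHE[(model_id, stage)]
    except KeyError:
        known = sorted(_CACHE)
        raise RegistryError(
            f"no registry entry for model {model_id!r} stage {stage!r}; "
            f"known entries: {known}"
        ) from None
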