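"""Shared run configuration: strict YAML schema with round-trip identity.

All values are SI (meters, seconds, W, J) with temperatures in Celsius;
unit conversion (e.g. mm) happens only at the CLI boundary.  Unknown keys
anywhere in the document are rejected, so a typo cannot silently fall back
to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .actuator import PeltierPlant
from .bioheat import (
    FROZEN_TUMOR_TISSUE,
    UNFROZEN_TUMOR_TISSUE,
    BloodPerfusion,
    FarBoundary,
    SlabGeometry,
    SlabProblem,
    SourceTerms,
    TissueProperties,
)
from .geometry import DEFAULT_BASELINE, DEFAULT_EPSILON
from .stehfest import DEFAULT_ORDER, StehfestScheme, stehfest_weights

__all__ = ["GridSpec", "RunConfig", "TISSUE_PRESETS"]

TISSUE_PRESETS = {
    "unfrozen_tumor": UNFROZEN_TUMOR_TISSUE,
    "frozen_tumor": FROZEN_TUMOR_TISSUE,
}


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration content."""


def _take(mapping: Mapping[str, Any], allowed: set[str], context: str) -> dict:
    if not isinstance(mapping, Mapping):
        raise ConfigError(f"{context} must be a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {context}")
    return dict(mapping)


@dataclass(frozen=True)
class GridSpec:
    """Uniform grid: ``num`` points from ``start`` to ``stop`` inclusive."""

    start: float
    stop: float
    num: int

    def __post_init__(self) -> None:
        if self.num < 1:
            raise ConfigError(f"grid num must be >= 1, got {self.num}")
        if self.stop < self.start:
            raise ConfigError("grid stop must be >= start")

    def points(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.num)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any], context: str) -> "GridSpec":
        d = _take(d, {"start", "stop", "num"}, context)
        return cls(float(d.get("start", 0.0)), float(d["stop"]), int(d["num"]))

    def to_dict(self) -> dict:
        return {"start": self.start, "stop": self.stop, "num": self.num}


def _tissue_from(entry: Any) -> TissueProperties:
    if isinstance(entry, str):
        if entry not in TISSUE_PRESETS:
            raise ConfigError(
                f"unknown tissue preset {entry!r}; options: {sorted(TISSUE_PRESETS)}"
            )
        return TISSUE_PRESETS[entry]
    d = _take(entry, {"density", "specific_heat", "conductivity"}, "problem.tissue")
    try:
        return TissueProperties(**{k: float(v) for k, v in d.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"problem.tissue: {exc}") from exc


def _problem_from(d: Mapping[str, Any]) -> SlabProblem:
    d = _take(
        d, {"tissue", "blood", "sources", "geometry", "initial_temperature"}, "problem"
    )
    tissue = _tissue_from(d.get("tissue", "unfrozen_tumor"))
    blood_d = _take(
        d.get("blood", {}),
        {"perfusion_rate", "blood_specific_heat", "arterial_temperature"},
        "problem.blood",
    )
    sources_d = _take(
        d.get("sources", {}), {"metabolic_heat", "surface_flux"}, "problem.sources"
    )
    geom_d = _take(d.get("geometry", {}), {"thickness", "far_boundary"}, "problem.geometry")
    try:
        return SlabProblem(
            tissue=tissue,
            blood=BloodPerfusion(**{k: float(v) for k, v in blood_d.items()}),
            sources=SourceTerms(**{k: float(v) for k, v in sources_d.items()}),
            geometry=SlabGeometry(
                thickness=float(geom_d.get("thickness", 0.007)),
                far_boundary=FarBoundary(geom_d.get("far_boundary", "dirichlet_initial")),
            ),
            initial_temperature=float(d.get("initial_temperature", 40.0)),
        )
    except ValueError as exc:
        raise ConfigError(f"problem: {exc}") from exc


def _problem_to(p: SlabProblem) -> dict:
    return {
        "tissue": {
            "density": p.tissue.density,
            "specific_heat": p.tissue.specific_heat,
            "conductivity": p.tissue.conductivity,
        },
        "blood": {
            "perfusion_rate": p.blood.perfusion_rate,
            "blood_specific_heat": p.blood.blood_specific_heat,
            "arterial_temperature": p.blood.arterial_temperature,
        },
        "sources": {
            "metabolic_heat": p.sources.metabolic_heat,
            "surface_flux": p.sources.surface_flux,
        },
        "geometry": {
            "thickness": p.geometry.thickness,
            "far_boundary": p.geometry.far_boundary.value,
        },
        "initial_temperature": p.initial_temperature,
    }


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    problem: SlabProblem | None = None  # None -> repository default problem
    scheme_order: int = DEFAULT_ORDER
    positions: GridSpec = GridSpec(0.0, 0.007, 30)
    times: GridSpec = GridSpec(0.0, 300.0, 121)
    epsilon: float = DEFAULT_EPSILON
    baseline: float = DEFAULT_BASELINE
    touch_dt: float = 0.01
    plant: PeltierPlant = PeltierPlant()
    loop_dt: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.problem is None:
            from .bioheat import default_problem

            object.__setattr__(self, "problem", default_problem())
        if not (self.epsilon > 0 and self.touch_dt > 0 and self.loop_dt > 0):
            raise ConfigError("epsilon, touch_dt and loop_dt must be positive")

    def scheme(self) -> StehfestScheme:
        return stehfest_weights(self.scheme_order)

    # -- serialisation ------------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = _take(
            d,
            {
                "problem",
                "scheme_order",
                "positions",
                "times",
                "touch",
                "plant",
                "seed",
            },
            "config",
        )
        touch = _take(d.get("touch", {}), {"epsilon", "baseline", "dt", "loop_dt"}, "touch")
        plant_d = _take(
            d.get("plant", {}),
            {
                "time_constant",
                "gain",
                "ambient",
                "max_temperature",
                "margin",
                "deadband",
                "error_span",
                "sensor_noise_sd",
            },
            "plant",
        )
        try:
            plant = PeltierPlant(**{k: float(v) for k, v in plant_d.items()})
        except ValueError as exc:
            raise ConfigError(f"plant: {exc}") from exc
        defaults = cls(problem=None)
        return cls(
            problem=_problem_from(d["problem"]) if "problem" in d else defaults.problem,
            scheme_order=int(d.get("scheme_order", DEFAULT_ORDER)),
            positions=(
                GridSpec.from_dict(d["positions"], "positions")
                if "positions" in d
                else defaults.positions
            ),
            times=GridSpec.from_dict(d["times"], "times") if "times" in d else defaults.times,
            epsilon=float(touch.get("epsilon", DEFAULT_EPSILON)),
            baseline=float(touch.get("baseline", DEFAULT_BASELINE)),
            touch_dt=float(touch.get("dt", 0.01)),
            plant=plant,
            loop_dt=float(touch.get("loop_dt", 0.005)),
            seed=int(d.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "problem": _problem_to(self.problem),
            "scheme_order": self.scheme_order,
            "positions": self.positions.to_dict(),
            "times": self.times.to_dict(),
            "touch": {
                "epsilon": self.epsilon,
                "baseline": self.baseline,
                "dt": self.touch_dt,
                "loop_dt": self.loop_dt,
            },
            "plant": {
                "time_constant": self.plant.time_constant,
                "gain": self.plant.gain,
                "ambient": self.plant.ambient,
                "max_temperature": self.plant.max_temperature,
                "margin": self.plant.margin,
                "deadband": self.plant.deadband,
                "error_span": self.plant.error_span,
                "sensor_noise_sd": self.plant.sensor_noise_sd,
            },
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        return cls.from_dict(data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text
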