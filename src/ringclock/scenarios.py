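"""Named simulation scenarios and YAML scenario configs.

The bundled scenarios reproduce the study's culture conditions: 12:12
LD entrainment at 20 C (one ring per day), free run in constant
darkness at 20/14/10 C with free-running periods of 24.5, 24.4 and
26.8 h, and the jet-lag protocol (an 8 h delay of the LD cycle after
four days of entrainment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .schedule import LightSchedule
from .synthetic import ClockParams, ColonyModel, IlluminationField

__all__ = ["Scenario", "get_scenario", "scenario_names", "scenario_from_yaml",
           "scenario_to_yaml", "FRP_BY_TEMPERATURE"]

#: Free-running periods (h) by culture temperature (C).
FRP_BY_TEMPERATURE = {10.0: 26.8, 14.0: 24.4, 20.0: 24.5}

#: Camera noise SD as a fraction of the 8-bit dynamic range.
DEFAULT_NOISE_FRACTION = 0.02


@dataclass(frozen=True)
class Scenario:
    """Everything the generator needs for one simulated plate."""

    name: str
    schedule: LightSchedule
    clock: ClockParams
    colony: ColonyModel
    illumination: IlluminationField = field(
        default_factory=lambda: IlluminationField(kind="planar", params={"gx": 0.10})
    )
    noise_sd: float = DEFAULT_NOISE_FRACTION * 255.0
    bit_depth: int = 8
    temperature_C: float | None = None


def _colony(duration: float, image_px: int = 1024) -> ColonyModel:
    center = (image_px / 2.0, image_px / 2.0)
    return ColonyModel(growth_rate=3.0, seed_center=center, start_radius=24.0,
                       duration=duration)


def _dd_scenario(name: str, temperature: float) -> Scenario:
    period = FRP_BY_TEMPERATURE[temperature]
    return Scenario(
        name=name,
        schedule=LightSchedule(dd_start=0.0),
        clock=ClockParams(free_running_period=period),
        colony=_colony(duration=144.0),
        temperature_C=temperature,
    )


def _builtin_scenarios() -> dict[str, Scenario]:
    scenarios = {
        "ld_20C": Scenario(
            name="ld_20C",
            schedule=LightSchedule(),
            clock=ClockParams(free_running_period=24.5),
            colony=_colony(duration=144.0),
            temperature_C=20.0,
        ),
        "ld_dd_20C": Scenario(
            name="ld_dd_20C",
            schedule=LightSchedule(dd_start=48.0),
            clock=ClockParams(free_running_period=24.5),
            colony=_colony(duration=192.0, image_px=1344),
            temperature_C=20.0,
        ),
        "dd_20C": _dd_scenario("dd_20C", 20.0),
        "dd_14C": _dd_scenario("dd_14C", 14.0),
        "dd_10C": _dd_scenario("dd_10C", 10.0),
        "jetlag_8h": Scenario(
            name="jetlag_8h",
            schedule=LightSchedule(shift_events=((96.0, 8.0),)),
            clock=ClockParams(free_running_period=24.5, relaxation_tau=36.0),
            colony=_colony(duration=240.0, image_px=1664),
            temperature_C=20.0,
        ),
    }
    return scenarios


def scenario_names() -> list[str]:
    return sorted(_builtin_scenarios())


def get_scenario(name: str) -> Scenario:
    scenarios = _builtin_scenarios()
    if name not in scenarios:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(scenarios)}")
    return scenarios[name]


# -- YAML round trip ---------------------------------------------------


def scenario_to_yaml(scenario: Scenario, path: str | Path) -> None:
    doc = {
        "name": scenario.name,
        "temperature_C": scenario.temperature_C,
        "schedule": {
            "cycle_length": scenario.schedule.cycle_length,
            "light_fraction": scenario.schedule.light_fraction,
            "phase_offset": scenario.schedule.phase_offset,
            "dd_start": scenario.schedule.dd_start,
            "shift_events": list(map(list, scenario.schedule.shift_events)),
        },
        "clock": {
            "free_running_period": scenario.clock.free_running_period,
            "entrained_phase": scenario.clock.entrained_phase,
            "relaxation_tau": scenario.clock.relaxation_tau,
        },
        "colony": {
            "growth_rate": scenario.colony.growth_rate,
            "seed_center": list(scenario.colony.seed_center),
            "start_radius": scenario.colony.start_radius,
            "duration": scenario.colony.duration,
            "baseline_intensity": scenario.colony.baseline_intensity,
            "ring_amplitude": scenario.colony.ring_amplitude,
            "ring_sharpness": scenario.colony.ring_sharpness,
            "ring_polarity": scenario.colony.ring_polarity,
        },
        "illumination": {"kind": scenario.illumination.kind,
                         "params": dict(scenario.illumination.params)},
        "noise_sd": scenario.noise_sd,
        "bit_depth": scenario.bit_depth,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def scenario_from_yaml(path: str | Path) -> Scenario:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        sched = doc["schedule"]
        schedule = LightSchedule(
            cycle_length=sched.get("cycle_length", 24.0),
            light_fraction=sched.get("light_fraction", 0.5),
            phase_offset=sched.get("phase_offset", 0.0),
            dd_start=sched.get("dd_start"),
            shift_events=tuple(map(tuple, sched.get("shift_events", []))),
        )
        clock = ClockParams(**doc.get("clock", {}))
        colony_doc = dict(doc.get("colony", {}))
        if "seed_center" in colony_doc:
            colony_doc["seed_center"] = tuple(colony_doc["seed_center"])
        colony = ColonyModel(**colony_doc)
        illum_doc = doc.get("illumination", {"kind": "planar", "params": {}})
        illumination = IlluminationField(kind=illum_doc.get("kind", "planar"),
                                         params=illum_doc.get("params", {}) or {})
        return Scenario(
            name=doc.get("name", Path(path).stem),
            schedule=schedule,
            clock=clock,
            colony=colony,
            illumination=illumination,
            noise_sd=float(doc.get("noise_sd", DEFAULT_NOISE_FRACTION * 255.0)),
            bit_depth=int(doc.get("bit_depth", 8)),
            temperature_C=doc.get("temperature_C"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid scenario config {path}: {exc}") from exc
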