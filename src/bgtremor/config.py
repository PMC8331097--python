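"""YAML configuration: defaults, validation, round-trip serialisation.

A config file is a mapping with up to five sections; every key is
optional and unknown keys are rejected by name::

    params:            # circuit parameters, keys as in the parameter table
      tauSNc: 9.2357
    simulation:
      duration: 300.0
      dt: 0.1
      method: euler          # or rk4
      clamp_nonnegative: false
      seed: 0
    schedule:          # list of timed multiplicative interventions
      - {time: 75.0, parameter: tauSNc, multiplier: 1.25}
    cohort:
      n_subjects: 20
      noise_low: 0.01
      noise_high: 0.02
    ga:                # genetic-algorithm overrides (see GAConfig)
      population: 30
      generations: 300

Angles are accepted in degrees where they appear in configs and stored in
radians internally; times are seconds everywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import GAConfig
from .circuit import (
    PARAM_NAMES,
    CircuitParameters,
    InterventionSchedule,
    SimulationConfig,
)
from .cohort import CohortSpec

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """A config file failed validation; the message names the key."""


_GA_FIELDS = {f.name for f in dataclasses.fields(GAConfig)}
_SIM_KEYS = {"duration", "dt", "method", "clamp_nonnegative", "seed"}
_COHORT_KEYS = {"n_subjects", "noise_low", "noise_high", "seed"}
_SECTIONS = {"params", "simulation", "schedule", "cohort", "ga"}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration: defaults merged under explicit overrides."""

    params: CircuitParameters = field(default_factory=CircuitParameters)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    schedule: InterventionSchedule = field(default_factory=InterventionSchedule)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    ga: GAConfig = field(default_factory=GAConfig)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "simulation": {
                "duration": self.simulation.duration,
                "dt": self.simulation.dt,
                "method": self.simulation.method,
                "clamp_nonnegative": self.simulation.clamp_nonnegative,
                "seed": self.simulation.seed,
            },
            "schedule": self.schedule.to_dicts(),
            "cohort": {
                "n_subjects": self.cohort.n_subjects,
                "noise_low": self.cohort.noise_low,
                "noise_high": self.cohort.noise_high,
                "seed": self.cohort.seed,
            },
            "ga": {k: getattr(self.ga, k) for k in sorted(_GA_FIELDS)},
        }


def _check_keys(section: str, mapping: dict, allowed: set[str]) -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown key {key!r} in section {section!r}")


def _build(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys("<root>", raw, _SECTIONS)

    params_raw = raw.get("params") or {}
    _check_keys("params", params_raw, set(PARAM_NAMES))
    try:
        params = CircuitParameters(**{k: float(v) for k, v in params_raw.items()})
    except ValueError as exc:
        raise ConfigError(f"invalid parameter value: {exc}") from exc

    sim_raw = dict(raw.get("simulation") or {})
    _check_keys("simulation", sim_raw, _SIM_KEYS)
    try:
        simulation = SimulationConfig(**sim_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulation setting: {exc}") from exc

    schedule_raw = raw.get("schedule") or []
    if not isinstance(schedule_raw, list):
        raise ConfigError("section 'schedule' must be a list")
    try:
        schedule = InterventionSchedule.from_dicts(schedule_raw)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed schedule entry: {exc}") from exc
    for iv in schedule:
        if iv.time > simulation.duration:
            raise ConfigError(
                f"intervention at t={iv.time} s lies beyond the "
                f"{simulation.duration} s horizon"
            )

    cohort_raw = dict(raw.get("cohort") or {})
    _check_keys("cohort", cohort_raw, _COHORT_KEYS)
    try:
        cohort = CohortSpec(**cohort_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid cohort setting: {exc}") from exc

    ga_raw = dict(raw.get("ga") or {})
    _check_keys("ga", ga_raw, _GA_FIELDS)
    if "weights" in ga_raw:
        ga_raw["weights"] = tuple(float(w) for w in ga_raw["weights"])
    try:
        ga = GAConfig(**ga_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid ga setting: {exc}") from exc

    return RunConfig(
        params=params, simulation=simulation, schedule=schedule,
        cohort=cohort, ga=ga,
    )


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config, merging explicit values over the defaults.

    ``overrides`` (same structure as the file) take precedence over the
    file contents; with neither, the full defaults are returned.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        raw = loaded
    for section, value in (overrides or {}).items():
        if isinstance(value, dict):
            merged = dict(raw.get(section) or {})
            merged.update(value)
            raw[section] = merged
        else:
            raw[section] = value
    return _build(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config so that ``load_config`` reproduces it exactly."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
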