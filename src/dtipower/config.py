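"""YAML configuration loading, validation and run manifests.

A scenario config is a flat key-value document; unset keys fall back to the
packaged cohort defaults, CLI overrides win over file values.  Unknown keys
are rejected with the offending key named.  Every run can emit a manifest
(JSON) recording the fully resolved parameters, seed and version, which is
sufficient to reproduce the outputs exactly.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import defaults
from .design import GridSpec
from .exceptions import ConfigError
from .power import Scenario
from .trajectory import DecreaseModel, ErrorModel, GroupDistribution

__all__ = ["load_config", "scenario_to_dict", "RunManifest", "emit_manifest"]

_SCENARIO_SCHEMA: dict[str, type] = {
    "patient_mean_fa": float,
    "patient_sd_fa": float,
    "control_mean_fa": float,
    "control_sd_fa": float,
    "rate_percent": float,
    "cv_percent": float,
    "anchor_fa": float,
    "sem": float,
    "t_days": float,
    "m": int,
    "n_per_group": int,
    "alpha": float,
    "iterations": int,
    "seed": int,
    "anchoring": str,
    "test": str,
}

# grid sweeps replace the scalar sweep axes with value lists
_GRID_ONLY_SCHEMA: dict[str, type] = {
    "rates": list,
    "sems": list,
    "t_days_values": list,
    "m_values": list,
    "n_values": list,
}
_GRID_SCHEMA = {
    **{k: v for k, v in _SCENARIO_SCHEMA.items() if k not in ("rate_percent", "sem", "t_days", "m", "n_per_group")},
    **_GRID_ONLY_SCHEMA,
}

_SCENARIO_DEFAULTS: dict[str, Any] = {
    "patient_mean_fa": defaults.PATIENT_GROUP.mean_fa,
    "patient_sd_fa": defaults.PATIENT_GROUP.sd_fa,
    "control_mean_fa": defaults.CONTROL_GROUP.mean_fa,
    "control_sd_fa": defaults.CONTROL_GROUP.sd_fa,
    "rate_percent": defaults.DEFAULT_RATE_PERCENT,
    "cv_percent": defaults.CV_PERCENT,
    "anchor_fa": defaults.PATIENT_GROUP.mean_fa,
    "sem": defaults.SEM_LOW,
    "t_days": defaults.DEFAULT_T_DAYS,
    "m": defaults.DEFAULT_M,
    "n_per_group": defaults.DEFAULT_N_PER_GROUP,
    "alpha": defaults.ALPHA,
    "iterations": defaults.ITERATIONS,
    "seed": 0,
    "anchoring": "group",
    "test": "student",
}

_GRID_DEFAULTS: dict[str, Any] = {
    **{k: v for k, v in _SCENARIO_DEFAULTS.items() if k in _GRID_SCHEMA},
    "rates": list(defaults.RATES_PERCENT),
    "sems": [defaults.SEM_LOW, defaults.SEM_HIGH],
    "t_days_values": list(defaults.T_DAYS_OPTIONS),
    "m_values": list(defaults.M_OPTIONS),
    "n_values": [10, 20, 30],
}


def _coerce(key: str, value: Any, typ: type) -> Any:
    try:
        if typ is float:
            if isinstance(value, bool):
                raise TypeError
            return float(value)
        if typ is int:
            if isinstance(value, bool) or (isinstance(value, float) and not value.is_integer()):
                raise TypeError
            return int(value)
        if typ is str:
            if not isinstance(value, str):
                raise TypeError
            return value
        if typ is list:
            if not isinstance(value, (list, tuple)) or len(value) == 0:
                raise TypeError
            return list(value)
    except (TypeError, ValueError):
        pass
    raise ConfigError(f"key {key!r}: expected {typ.__name__}, got {value!r}")


def _resolve(
    schema: Mapping[str, type],
    base: Mapping[str, Any],
    file_values: Mapping[str, Any],
    overrides: Mapping[str, Any],
) -> dict[str, Any]:
    resolved = dict(base)
    for source_name, source in (("config file", file_values), ("override", overrides)):
        for key, value in source.items():
            if value is None:
                continue
            if key not in schema:
                raise ConfigError(f"unknown {source_name} key {key!r}")
            resolved[key] = _coerce(key, value, schema[key])
    return resolved


def _build_scenario(v: Mapping[str, Any]) -> Scenario:
    try:
        return Scenario(
            patient_group=GroupDistribution(v["patient_mean_fa"], v["patient_sd_fa"]),
            control_group=GroupDistribution(v["control_mean_fa"], v["control_sd_fa"]),
            decrease=DecreaseModel(v["rate_percent"], v["cv_percent"], v["anchor_fa"]),
            error=ErrorModel(v["sem"]),
            t_days=v["t_days"],
            m=v["m"],
            n_per_group=v["n_per_group"],
            alpha=v["alpha"],
            iterations=v["iterations"],
            seed=v["seed"],
            anchoring=v["anchoring"],
            test=v["test"],
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
    kind: str = "scenario",
) -> Scenario | GridSpec:
    """Resolve defaults, an optional YAML file and overrides into a validated
    :class:`Scenario` (``kind="scenario"``) or :class:`GridSpec` (``kind="grid"``)."""
    if kind not in ("scenario", "grid"):
        raise ConfigError(f"kind must be 'scenario' or 'grid', got {kind!r}")
    file_values: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        file_values = loaded
    overrides = dict(overrides or {})

    if kind == "scenario":
        v = _resolve(_SCENARIO_SCHEMA, _SCENARIO_DEFAULTS, file_values, overrides)
        return _build_scenario(v)

    v = _resolve(_GRID_SCHEMA, _GRID_DEFAULTS, file_values, overrides)
    template = _build_scenario(
        {
            **v,
            "rate_percent": v["rates"][0],
            "sem": v["sems"][0],
            "t_days": v["t_days_values"][0],
            "m": int(v["m_values"][0]),
            "n_per_group": int(v["n_values"][0]),
        }
    )
    try:
        return GridSpec(
            scenario_template=template,
            rates=[float(x) for x in v["rates"]],
            sems=[float(x) for x in v["sems"]],
            t_days_values=[float(x) for x in v["t_days_values"]],
            m_values=[int(x) for x in v["m_values"]],
            n_values=[int(x) for x in v["n_values"]],
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def scenario_to_dict(scenario: Scenario) -> dict[str, Any]:
    """Flat config-schema dict of a scenario (round-trips via load_config)."""
    return {
        "patient_mean_fa": scenario.patient_group.mean_fa,
        "patient_sd_fa": scenario.patient_group.sd_fa,
        "control_mean_fa": scenario.control_group.mean_fa,
        "control_sd_fa": scenario.control_group.sd_fa,
        "rate_percent": scenario.decrease.annual_rate_percent,
        "cv_percent": scenario.decrease.cv_percent,
        "anchor_fa": scenario.decrease.anchor_fa,
        "sem": scenario.error.sem,
        "t_days": scenario.t_days,
        "m": scenario.m,
        "n_per_group": scenario.n_per_group,
        "alpha": scenario.alpha,
        "iterations": scenario.iterations,
        "seed": scenario.seed,
        "anchoring": scenario.anchoring,
        "test": scenario.test,
    }


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Reproducibility record of one run: resolved parameters, seed, version."""

    command: str
    parameters: dict[str, Any]
    seed: int
    version: str
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )


def emit_manifest(run: RunManifest, path: str | Path) -> None:
    """Write the manifest as indented JSON (human-readable and parseable)."""
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(run), fh, indent=2, sort_keys=True)
        fh.write("\n")
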