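"""Configuration files, unit handling, manifests and atomic output.

Configuration is a YAML file whose keys mirror the model parameter names.
Dimensioned values are written as ``"<number> <unit>"`` strings so every key
declares its unit explicitly; lengths are normalized to millimetres and times
to milliseconds internally (interfaces accept cm/m and s as well).  Unknown
keys are rejected rather than ignored.

Every CLI invocation writes a run manifest (command, config snapshot, seed,
package version, output paths, timestamp) alongside its outputs, and all
outputs are written atomically (temp file, then rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import yaml

from .model import ModelParams, ParameterError, Priors

__all__ = [
    "ConfigError",
    "SimulationDefaults",
    "Config",
    "parse_quantity",
    "format_quantity",
    "load_config",
    "write_config",
    "default_config_path",
    "load_default_config",
    "atomic_write_text",
    "write_manifest",
]

_LENGTH_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}
_TIME_TO_MS = {"ms": 1.0, "s": 1000.0}


class ConfigError(ValueError):
    """Malformed or invalid configuration."""


def parse_quantity(value, dimension: str, key: str = "") -> float:
    """Parse ``"15 mm"`` / ``"0.75 s"``-style strings to canonical units
    (mm for lengths, ms for times).  Bare numbers are only accepted for
    dimensionless quantities."""
    where = f" for key {key!r}" if key else ""
    if dimension == "dimensionless":
        try:
            return float(value)
        except (TypeError, ValueError):
            raise ConfigError(f"expected a number{where}, got {value!r}") from None
    table = _LENGTH_TO_MM if dimension == "length" else _TIME_TO_MS
    if isinstance(value, (int, float)):
        raise ConfigError(
            f"missing unit{where}: write e.g. '{value} {next(iter(table))}'"
        )
    parts = str(value).split()
    if len(parts) != 2:
        raise ConfigError(f"cannot parse quantity {value!r}{where}")
    num, unit = parts
    if unit not in table:
        raise ConfigError(
            f"unknown {dimension} unit {unit!r}{where}; expected one of {sorted(table)}"
        )
    try:
        return float(num) * table[unit]
    except ValueError:
        raise ConfigError(f"cannot parse number in {value!r}{where}") from None


def format_quantity(value_canonical: float, dimension: str) -> str:
    unit = "mm" if dimension == "length" else "ms"
    return f"{value_canonical!r} {unit}"


@dataclass(frozen=True)
class SimulationDefaults:
    default_trials: int = 100_000
    illusion_threshold: float = 0.5
    async_offset: float = 750.0     # ms
    true_x_v: float = 160.0         # mm
    true_x_p: float = 320.0         # mm


@dataclass(frozen=True)
class Config:
    model: ModelParams
    simulation: SimulationDefaults = field(default_factory=SimulationDefaults)
    calibration: dict = field(default_factory=dict)


_MODEL_KEYS = {
    "sigma_v": "length", "sigma_p": "length",
    "sigma_tv": "time", "sigma_tt": "time",
    "include_temporal": None, "priors": None,
}
_PRIOR_KEYS = {
    "mu_x": "length", "sigma_x": "length",
    "mu_t": "time", "sigma_t": "time",
    "p_common": "dimensionless",
}
_SIM_KEYS = {
    "default_trials": "dimensionless", "illusion_threshold": "dimensionless",
    "async_offset": "time", "true_x_v": "length", "true_x_p": "length",
}
_CALIBRATION_KEYS = {"target_vanish_distance", "method", "generated_by", "timestamp"}


def _check_keys(section: dict, allowed, where: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_config(path) -> Config:
    """Load and validate a configuration file, normalizing units."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, {"model", "simulation", "calibration"}, "top level")
    model_raw = raw.get("model")
    if not isinstance(model_raw, dict):
        raise ConfigError("missing 'model' section")
    _check_keys(model_raw, _MODEL_KEYS, "'model'")
    priors_raw = model_raw.get("priors", {})
    if not isinstance(priors_raw, dict):
        raise ConfigError("'model.priors' must be a mapping")
    _check_keys(priors_raw, _PRIOR_KEYS, "'model.priors'")
    prior_kwargs = {
        k: parse_quantity(priors_raw[k], dim, key=f"model.priors.{k}")
        for k, dim in _PRIOR_KEYS.items()
        if k in priors_raw
    }
    model_kwargs = {}
    for k, dim in _MODEL_KEYS.items():
        if k not in model_raw or k == "priors":
            continue
        if k == "include_temporal":
            v = model_raw[k]
            if not isinstance(v, bool):
                raise ConfigError("model.include_temporal must be a boolean")
            model_kwargs[k] = v
        else:
            model_kwargs[k] = parse_quantity(model_raw[k], dim, key=f"model.{k}")
    try:
        params = ModelParams(priors=Priors(**prior_kwargs), **model_kwargs)
        params.validate()
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc
    sim_raw = raw.get("simulation", {})
    _check_keys(sim_raw, _SIM_KEYS, "'simulation'")
    sim_kwargs = {}
    for k, dim in _SIM_KEYS.items():
        if k in sim_raw:
            v = parse_quantity(sim_raw[k], dim, key=f"simulation.{k}")
            sim_kwargs[k] = int(v) if k == "default_trials" else v
    cal_raw = raw.get("calibration", {})
    _check_keys(cal_raw, _CALIBRATION_KEYS, "'calibration'")
    return Config(
        model=params,
        simulation=SimulationDefaults(**sim_kwargs),
        calibration=dict(cal_raw),
    )


def write_config(config: Config, path) -> None:
    """Serialize a configuration back to the documented YAML dialect (units
    declared per key; full float precision via ``repr``)."""
    m, pr = config.model, config.model.priors
    doc = {
        "model": {
            "sigma_v": format_quantity(m.sigma_v, "length"),
            "sigma_p": format_quantity(m.sigma_p, "length"),
            "sigma_tv": format_quantity(m.sigma_tv, "time"),
            "sigma_tt": format_quantity(m.sigma_tt, "time"),
            "include_temporal": m.include_temporal,
            "priors": {
                "mu_x": format_quantity(pr.mu_x, "length"),
                "sigma_x": format_quantity(pr.sigma_x, "length"),
                "mu_t": format_quantity(pr.mu_t, "time"),
                "sigma_t": format_quantity(pr.sigma_t, "time"),
                "p_common": pr.p_common,
            },
        },
        "simulation": {
            "default_trials": config.simulation.default_trials,
            "illusion_threshold": config.simulation.illusion_threshold,
            "async_offset": format_quantity(config.simulation.async_offset, "time"),
            "true_x_v": format_quantity(config.simulation.true_x_v, "length"),
            "true_x_p": format_quantity(config.simulation.true_x_p, "length"),
        },
    }
    if config.calibration:
        doc["calibration"] = dict(config.calibration)
    atomic_write_text(path, yaml.safe_dump(doc, sort_keys=False))


def default_config_path() -> Path:
    return Path(__file__).parent / "data" / "default_config.yaml"


def load_default_config() -> Config:
    """The shipped default configuration; its prior widths were produced by
    :func:`rhibayes.simulate.calibrate_prior_width` (see the file's
    ``calibration`` section for provenance)."""
    return load_config(default_config_path())


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------


def atomic_write_text(path, text: str) -> None:
    """Write text via a temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_manifest(
    out_path,
    command: str,
    seed: Optional[int],
    config: Optional[Config],
    outputs: list,
    timestamp: Optional[str] = None,
) -> Path:
    """Write the run manifest next to the first output."""
    snapshot = None
    config_hash = None
    if config is not None:
        snapshot = {
            "model": dataclasses.asdict(config.model),
            "simulation": dataclasses.asdict(config.simulation),
            "calibration": config.calibration,
        }
        config_hash = hashlib.sha256(
            json.dumps(snapshot, sort_keys=True).encode()
        ).hexdigest()[:16]
    manifest = {
        "command": command,
        "seed": seed,
        "package_version": _package_version(),
        "config": snapshot,
        "config_hash": config_hash,
        "outputs": [str(o) for o in outputs],
        "timestamp": timestamp
        or datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    out_path = Path(out_path)
    atomic_write_text(out_path, json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_path


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("rhibayes")
    except PackageNotFoundError:
        return "unknown"
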