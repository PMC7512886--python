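"""Flat config-file handling for parameters, forcing and run settings.

Configs are flat TOML or JSON mappings with keys ``a, b, c, d`` (model
coefficients), ``A, B, omega, target`` (forcing; ``target`` may also be a
scenario name via ``scenario``) and optional run-settings keys
``dt, t0, transient_periods, record_periods, R0, J0``.  Unknown keys are
rejected so that typos fail loudly rather than silently falling back to
defaults.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

from . import defaults
from .integrate import RunSettings
from .model import ForcingSpec, ForcingTarget, LoveParams, State, scenario

__all__ = ["RunConfig", "load_config", "dump_config"]

_PARAM_KEYS = {"a", "b", "c", "d"}
_FORCING_KEYS = {"A", "B", "omega", "target", "scenario"}
_SETTINGS_KEYS = {"dt", "t0", "transient_periods", "record_periods", "R0", "J0"}
_ALL_KEYS = _PARAM_KEYS | _FORCING_KEYS | _SETTINGS_KEYS


@dataclass(frozen=True)
class RunConfig:
    """A fully validated (params, forcing, settings) triple."""

    params: LoveParams
    forcing: ForcingSpec
    settings: RunSettings

    def to_dict(self) -> dict:
        p, f, s = self.params, self.forcing, self.settings
        return {
            "a": p.a, "b": p.b, "c": p.c, "d": p.d,
            "A": f.A, "B": f.B, "omega": f.omega, "target": f.target.value,
            "dt": s.dt, "t0": s.t0,
            "transient_periods": s.transient_periods,
            "record_periods": s.record_periods,
            "R0": s.initial_state.R, "J0": s.initial_state.J,
        }


def from_mapping(data: dict) -> RunConfig:
    """Build a validated RunConfig from a flat mapping."""
    unknown = set(data) - _ALL_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "scenario" in data and ({"A", "B", "omega"} & set(data)):
        raise ValueError("give either a scenario name or explicit A/B/omega, not both")

    params = LoveParams(
        a=float(data.get("a", defaults.REGIME_A_VALUES[0])),
        b=float(data.get("b", defaults.CANONICAL_B)),
        c=float(data.get("c", defaults.CANONICAL_C)),
        d=float(data.get("d", defaults.CANONICAL_D)),
    )
    if "scenario" in data:
        forcing = scenario(data["scenario"])
        if "target" in data:
            raise ValueError("target cannot be overridden for a named scenario")
    else:
        forcing = ForcingSpec(
            A=float(data.get("A", 5.0)),
            B=float(data.get("B", 0.0)),
            omega=float(data.get("omega", 1.0)),
            target=ForcingTarget(data.get("target", "romeo")),
        )
    settings = RunSettings(
        dt=float(data.get("dt", defaults.DT)),
        t0=float(data.get("t0", 0.0)),
        transient_periods=int(data.get("transient_periods", defaults.TRANSIENT_PERIODS)),
        record_periods=int(data.get("record_periods", defaults.RECORD_PERIODS)),
        initial_state=State(
            float(data.get("R0", defaults.INITIAL_STATE[0])),
            float(data.get("J0", defaults.INITIAL_STATE[1])),
        ),
    )
    settings.steps_per_period(forcing)  # validate dt divides the period
    return RunConfig(params=params, forcing=forcing, settings=settings)


def load_config(path) -> RunConfig:
    """Load a TOML (.toml) or JSON (.json) config file."""
    path = Path(path)
    if path.suffix == ".toml":
        data = tomllib.loads(path.read_text())
    elif path.suffix == ".json":
        data = json.loads(path.read_text())
    else:
        raise ValueError(f"config must be .toml or .json, got {path.suffix!r}")
    if not isinstance(data, dict):
        raise ValueError("config must be a flat mapping")
    return from_mapping(data)


def dump_config(cfg: RunConfig, path) -> None:
    """Write a config as JSON (round-trips through :func:`load_config`)."""
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
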