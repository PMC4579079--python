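"""Run configuration: TOML parsing, validation, defaults, provenance."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .params import RiskParams

__all__ = ["RunConfig", "load_config", "save_config", "provenance_record"]

_TOP_LEVEL_KEYS = {"seed", "years", "start_year", "log_level"}
_SECTIONS = {"params", "scenario", "perturbation", "paths"}
_SCENARIO_KEYS = {"rate", "region"}
_PERTURBATION_KEYS = {"ppe_amplitude", "stochastic_sigma"}


@dataclass
class RunConfig:
    """Validated configuration for a simulation run.

    An empty file is a valid config: every model constant falls back to
    the reference-experiment default in :class:`RiskParams`, the
    scenario to a single region at the Congo demonstration rate
    (-0.0001 yr-1 net), and the perturbations to off.
    """

    seed: int = 0
    years: int = 9
    start_year: int = 2001
    log_level: str = "INFO"
    params: RiskParams = field(default_factory=RiskParams)
    scenario_rate: float = -0.0001
    scenario_region: int = 1
    ppe_amplitude: float = 0.0
    stochastic_sigma: float = 0.0
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "years": self.years,
            "start_year": self.start_year,
            "log_level": self.log_level,
            "params": self.params.to_dict(),
            "scenario": {"rate": self.scenario_rate, "region": self.scenario_region},
            "perturbation": {
                "ppe_amplitude": self.ppe_amplitude,
                "stochastic_sigma": self.stochastic_sigma,
            },
            "paths": dict(self.paths),
        }
        return d


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration.

    Unknown keys (top-level or within a section) and out-of-range
    parameter values raise with the offending key named.
    """
    raw = tomllib.loads(Path(path).read_text())
    unknown = set(raw) - _TOP_LEVEL_KEYS - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")

    cfg = RunConfig()
    for key in _TOP_LEVEL_KEYS & set(raw):
        setattr(cfg, key, raw[key])
    if cfg.years < 1:
        raise ValueError("years must be >= 1")

    params_raw = raw.get("params", {})
    try:
        cfg.params = RiskParams().with_overrides(**params_raw)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"invalid [params] section: {exc}") from exc

    scen = raw.get("scenario", {})
    bad = set(scen) - _SCENARIO_KEYS
    if bad:
        raise ValueError(f"unknown [scenario] key(s): {sorted(bad)}")
    cfg.scenario_rate = float(scen.get("rate", cfg.scenario_rate))
    cfg.scenario_region = int(scen.get("region", cfg.scenario_region))

    pert = raw.get("perturbation", {})
    bad = set(pert) - _PERTURBATION_KEYS
    if bad:
        raise ValueError(f"unknown [perturbation] key(s): {sorted(bad)}")
    cfg.ppe_amplitude = float(pert.get("ppe_amplitude", 0.0))
    cfg.stochastic_sigma = float(pert.get("stochastic_sigma", 0.0))
    if cfg.ppe_amplitude < 0 or cfg.stochastic_sigma < 0:
        raise ValueError("perturbation amplitudes must be >= 0")

    cfg.paths = dict(raw.get("paths", {}))
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return json.dumps(str(v))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config back to TOML such that load(save(x)) == x."""
    lines = [
        f"seed = {cfg.seed}",
        f"years = {cfg.years}",
        f"start_year = {cfg.start_year}",
        f"log_level = {_toml_value(cfg.log_level)}",
        "",
        "[params]",
    ]
    for key, val in cfg.params.to_dict().items():
        lines.append(f"{key} = {_toml_value(val)}")
    lines += [
        "",
        "[scenario]",
        f"rate = {_toml_value(cfg.scenario_rate)}",
        f"region = {cfg.scenario_region}",
        "",
        "[perturbation]",
        f"ppe_amplitude = {_toml_value(cfg.ppe_amplitude)}",
        f"stochastic_sigma = {_toml_value(cfg.stochastic_sigma)}",
    ]
    if cfg.paths:
        lines += ["", "[paths]"]
        for key, val in cfg.paths.items():
            lines.append(f"{key} = {_toml_value(val)}")
    Path(path).write_text("\n".join(lines) + "\n")


def provenance_record(cfg: RunConfig) -> dict:
    """Config hash + seed + software version, written alongside outputs."""
    from . import __version__

    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg.seed,
        "version": __version__,
    }
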