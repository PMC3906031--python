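"""Run configuration: YAML loading with strict key validation.

The configuration mirrors the module structure (growth / mdf /
connectivity / network / efficiency / experiment sections plus a master
seed and an output directory).  Unknown keys are rejected with the
offending key named, so typos fail loudly instead of silently falling
back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .morphogen import GrowthParams

_GROWTH_KEYS = {f.name for f in dataclasses.fields(GrowthParams)}

_SCHEMA: dict[str, set[str]] = {
    "growth": _GROWTH_KEYS,
    "mdf": {"h", "r_max", "z_min", "z_max", "kind"},
    "connectivity": {"s", "integration_step", "sigma", "method",
                     "rho", "zeta"},
    "network": {"n", "radius", "height", "min_distance"},
    "efficiency": set(),
    "experiment": {"sizes", "n_replicates", "displacements", "n_neurons",
                   "sigmas", "shapes", "n", "n_morphologies", "lattice_step",
                   "rho_max", "zeta_max"},
}
_TOP_KEYS = set(_SCHEMA) | {"seed", "out_dir"}


@dataclass
class RunConfig:
    """Validated nested configuration for a CLI run."""

    seed: int = 0
    out_dir: str = "."
    growth: dict = field(default_factory=dict)
    mdf: dict = field(default_factory=dict)
    connectivity: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    efficiency: dict = field(default_factory=dict)
    experiment: dict = field(default_factory=dict)

    def growth_params(self) -> GrowthParams:
        kw = dict(self.growth)
        for key in ("n_basal_range",):
            if key in kw:
                kw[key] = tuple(kw[key])
        return GrowthParams(**kw).validate()

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def write_resolved(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.resolved(), fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def validate_config_dict(raw: dict) -> None:
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration root must be a mapping")
    for key, value in raw.items():
        if key not in _TOP_KEYS:
            raise ConfigurationError(f"unknown configuration key: {key!r}")
        if key in _SCHEMA:
            if not isinstance(value, dict):
                raise ConfigurationError(f"section {key!r} must be a mapping")
            for sub in value:
                if sub not in _SCHEMA[key]:
                    raise ConfigurationError(
                        f"unknown configuration key: {key}.{sub}")


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        raw.update(loaded)
    validate_config_dict(raw)
    cfg = RunConfig(**raw)
    if overrides:
        for dotted, value in overrides.items():
            if value is None:
                continue
            if "." in dotted:
                section, sub = dotted.split(".", 1)
                getattr(cfg, section)[sub] = value
            else:
                setattr(cfg, dotted, value)
    validate_config_dict({k: v for k, v in cfg.resolved().items()
                          if v not in (None, {})})
    return cfg


def ensure_out_dir(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out
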