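"""Run configuration: YAML loading, defaults, and provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = ["RunConfig", "load_config", "config_hash"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "verbosity": "INFO",
    "paths": {
        "records": "results/records.csv",
        "climate": "results/climate.csv",
        "survival_schedule": None,
        "output_dir": "results",
    },
    "analysis": {
        "outcome": "parturition",
        "age_scheme": "default",
        "reference": {
            "snow_ref": 1.29,
            "temp_ref": 7.8,
            "snow_range": [0.01, 2.64],
            "temp_range": [6.00, 9.34],
        },
        "n_nodes": 21,
    },
    "projection": {
        "n_age_classes": 20,
        "neonate_survival": 0.90,
        "sex_ratio_female": 0.5,
        "fecundity_sd": 0.106,
        "horizon": 30,
        "n_sims": 10000,
        "n0": 100,
        "coef_uncertainty": False,
    },
    "generator": {
        "n_individuals": 180,
        "n_sites": 3,
        "n_years": 17,
        "sigma_u": 0.7,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Merged configuration for one pipeline invocation."""

    data: dict[str, Any] = field(default_factory=lambda: json.loads(json.dumps(DEFAULTS)))

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def hash(self) -> str:
        return config_hash(self.data)

    def header_lines(self) -> list[str]:
        return [f"seed={self.seed}", f"config_hash={self.hash()}"]


def config_hash(data: dict) -> str:
    canonical = json.dumps(data, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> RunConfig:
    data = json.loads(json.dumps(DEFAULTS))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        data = _merge(data, user)
    if overrides:
        data = _merge(data, overrides)
    return RunConfig(data=data)
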