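"""Run configuration, manifests and file exports.

Outputs are plain CSV (RFC-4180, UTF-8, '.' decimal); every run
directory receives a machine-readable manifest recording the config
hash, seed, package version and wall time so results can be traced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .parameters import ConfigurationError, ParameterSet, build_default_parameters

__all__ = ["ScenarioConfig", "load_config", "write_manifest", "logger"]

logger = logging.getLogger("g2mcycle")

_ALLOWED_KEYS = {
    "label", "parameter_table", "conservation_table", "seed",
    "p53_null", "plk1_depletion", "t_end", "burn_in", "rtol", "atol",
    "perturbations", "sensitivity", "grids",
}


@dataclass
class ScenarioConfig:
    """Validated YAML run configuration."""

    label: str = "wildtype"
    parameter_table: Optional[str] = None
    conservation_table: Optional[str] = None
    seed: int = 0
    p53_null: bool = False
    plk1_depletion: float = 0.0
    t_end: float = 400.0
    burn_in: float = 100.0
    rtol: float = 1e-6
    atol: float = 1e-9
    perturbations: list = field(default_factory=list)
    sensitivity: Dict[str, Any] = field(default_factory=dict)
    grids: Dict[str, Any] = field(default_factory=dict)

    def load_parameters(self) -> ParameterSet:
        return build_default_parameters(self.parameter_table)

    def to_dict(self) -> Dict[str, Any]:
        return {k: getattr(self, k) for k in sorted(_ALLOWED_KEYS)}

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: Optional[str]) -> ScenarioConfig:
    if path is None:
        return ScenarioConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown config keys: {', '.join(sorted(unknown))}")
    if "plk1_depletion" in raw and not 0 <= raw["plk1_depletion"] <= 1:
        raise ConfigurationError("plk1_depletion must be in [0, 1]")
    return ScenarioConfig(**raw)


def write_manifest(out_dir, config: ScenarioConfig, seed: int,
                   started: float, extra: Optional[Dict[str, Any]] = None) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": seed,
        "version": __version__,
        "wall_time_s": round(time.time() - started, 3),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
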