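"""Configuration loading/validation and run manifests.

A single YAML file carries every model input — the fitted Weibull survival
parameters for each arm and endpoint, the structural model settings, and
all economic parameters with their sensitivity ranges — so that no number
is hard-coded in analysis logic.  ``load_config()`` with no argument loads
the packaged base-case configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .economics import SAE_KEYS, EconomicInputs, Parameter
from .markov import Arm, ModelConfig
from .survival import WeibullParams

__all__ = ["load_config", "default_config_path", "RunManifest", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


def default_config_path() -> Path:
    """Filesystem path of the packaged base-case configuration."""
    return Path(resources.files("olacea") / "data" / "default_config.yaml")


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"missing required field {context}.{key}")
    return mapping[key]


def _parameter(entry: dict, context: str) -> Parameter:
    try:
        return Parameter(
            float(_require(entry, "base", context)),
            float(_require(entry, "low", context)),
            float(_require(entry, "high", context)),
            entry.get("distribution", "fixed"),
        )
    except ValueError as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def _weibull(entry: dict, context: str) -> WeibullParams:
    try:
        return WeibullParams(
            float(_require(entry, "scale", context)),
            float(_require(entry, "shape", context)),
            float(entry.get("scale_se", 0.0)),
            float(entry.get("shape_se", 0.0)),
            tuple(entry["scale_ci"]) if "scale_ci" in entry else None,
            tuple(entry["shape_ci"]) if "shape_ci" in entry else None,
        )
    except ValueError as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def load_config(path=None) -> Tuple[ModelConfig, EconomicInputs, Dict[str, Arm], float]:
    """Load and validate a model configuration.

    Returns ``(model_config, economic_inputs, arms, wtp_threshold)``.
    ``path=None`` loads the packaged base-case configuration.
    """
    if path is None:
        path = default_config_path()
    raw = yaml.safe_load(Path(path).read_text())

    m = _require(raw, "model", "<root>")
    try:
        config = ModelConfig(
            horizon=int(m.get("horizon_cycles", 120)),
            annual_discount_rate=float(m.get("annual_discount_rate", 0.03)),
            background_annual_mortality=float(m.get("background_annual_mortality", 0.00707)),
            half_cycle_correction=bool(m.get("half_cycle_correction", True)),
            engine_mode=m.get("engine_mode", "partitioned_survival"),
            background_mortality_in_partitioned=bool(
                m.get("background_mortality_in_partitioned", False)
            ),
        )
    except ValueError as exc:
        raise ConfigError(f"model: {exc}") from exc

    surv = _require(raw, "survival", "<root>")
    arms: Dict[str, Arm] = {}
    for arm_name in ("olaparib", "placebo"):
        entry = _require(surv, arm_name, "survival")
        arms[arm_name] = Arm(
            arm_name,
            _weibull(_require(entry, "pfs", f"survival.{arm_name}"),
                     f"survival.{arm_name}.pfs"),
            _weibull(_require(entry, "os", f"survival.{arm_name}"),
                     f"survival.{arm_name}.os"),
        )

    eco = _require(raw, "economics", "<root>")
    scalar_fields = [
        "olaparib_price_per_150mg", "brca_testing", "followup_per_cycle",
        "radiology_per_cycle", "salvage_per_cycle", "terminal_care",
        "utility_pfs", "utility_pd", "bsa", "discount_rate",
    ]
    kwargs = {name: _parameter(_require(eco, name, "economics"), f"economics.{name}")
              for name in scalar_fields}
    for map_name in ("sae_unit_costs", "sae_risks_olaparib", "sae_risks_placebo"):
        entry = _require(eco, map_name, "economics")
        kwargs[map_name] = {
            key: _parameter(_require(entry, key, f"economics.{map_name}"),
                            f"economics.{map_name}.{key}")
            for key in SAE_KEYS
        }
    try:
        inputs = EconomicInputs(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    wtp = float(raw.get("wtp_threshold", 31498.70))
    return config, inputs, arms, wtp


@dataclass
class RunManifest:
    """Provenance record for one analysis run."""

    config_digest: str
    seed: Optional[int]
    engine_mode: str
    package_version: str
    started_utc: str
    outputs: List[str] = field(default_factory=list)

    @classmethod
    def start(cls, config_path, seed: Optional[int], engine_mode: str) -> "RunManifest":
        from . import __version__

        text = Path(config_path).read_bytes()
        return cls(
            config_digest=hashlib.sha256(text).hexdigest(),
            seed=seed,
            engine_mode=engine_mode,
            package_version=__version__,
            started_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def record(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")
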