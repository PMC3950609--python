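"""Key-value configuration: membrane constants, channel table, protocols.

The packaged defaults (``rgcsim/data/defaults.yaml``) hold every printed
model constant; a user file with the same structure overrides individual
keys, and every override is logged so non-standard runs are identifiable.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import yaml

from .membrane import DistributionTable, MembraneConstants
from .simulator import SimulationConfig

logger = logging.getLogger(__name__)


def _defaults() -> dict:
    text = (resources.files("rgcsim") / "data" / "defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    """Merged configuration dictionary (defaults, then user overrides)."""
    cfg = _defaults()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in user.items():
            if not isinstance(values, dict):
                logger.info("config override: %s = %r", section, values)
                cfg[section] = values
                continue
            for key, value in values.items():
                if cfg.get(section, {}).get(key) != value:
                    logger.info("config override: %s.%s = %r",
                                section, key, value)
                cfg.setdefault(section, {})[key] = value
    return cfg


def membrane_constants(cfg: dict) -> MembraneConstants:
    return MembraneConstants(**cfg.get("membrane", {}))


def distribution_table(cfg: dict) -> DistributionTable:
    section = {k: tuple(v) if isinstance(v, list) else v
               for k, v in cfg.get("distribution", {}).items()}
    return DistributionTable(**section)


def simulation_config(cfg: dict) -> SimulationConfig:
    section = dict(cfg.get("simulation", {}))
    if "record_sites" in section:
        section["record_sites"] = tuple(section["record_sites"])
    return SimulationConfig(**section)
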