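"""Thin readers/writers for the package's plain-text interchange formats.

Time series travel as long-format CSV (columns ``well, time_h, channel,
value``; one header row, UTF-8, '.' decimal separator); configuration as
YAML or JSON mirroring the config dataclass field names.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .synthetic_data import GrowthModelConfig, SecretionEffectConfig

__all__ = [
    "read_timeseries_csv",
    "write_timeseries_csv",
    "load_growth_config",
    "load_secretion_config",
]

_TS_COLUMNS = ["well", "time_h", "channel", "value"]


def write_timeseries_csv(ts: pd.DataFrame, path: str | Path) -> None:
    missing = set(_TS_COLUMNS) - set(ts.columns)
    if missing:
        raise ValueError(f"time series lacks columns {sorted(missing)}")
    ts[_TS_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_timeseries_csv(path: str | Path) -> pd.DataFrame:
    ts = pd.read_csv(path, encoding="utf-8")
    missing = set(_TS_COLUMNS) - set(ts.columns)
    if missing:
        raise ValueError(f"{path}: expected columns {_TS_COLUMNS}")
    return ts


def _load_mapping(path: str | Path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_growth_config(path: str | Path) -> GrowthModelConfig:
    """Load a growth-model config from YAML or JSON."""
    return GrowthModelConfig(**_load_mapping(path))


def load_secretion_config(path: str | Path) -> SecretionEffectConfig:
    """Load a secretion-effect config from YAML or JSON."""
    return SecretionEffectConfig(**_load_mapping(path))
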