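"""Table/config I/O helpers shared by the CLI and library users."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .bulk_models import BULK_COLUMNS
from .memory_metrics import SPOT_COLUMNS
from .simulator import POPULATION_COLUMNS

__all__ = [
    "read_bulk_series",
    "read_spot_table",
    "read_population",
    "read_standards",
    "load_config",
    "write_result_json",
]


def _read_csv_checked(path, required: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{what} file {path!s} is missing required column(s): "
            + ", ".join(missing)
        )
    return df


def read_bulk_series(path) -> pd.DataFrame:
    return _read_csv_checked(path, BULK_COLUMNS, "bulk qPCR series")


def read_spot_table(path) -> pd.DataFrame:
    required = [c for c in SPOT_COLUMNS if c != "spot_id"]
    return _read_csv_checked(path, required, "spot table")


def read_population(path) -> pd.DataFrame:
    return _read_csv_checked(path, POPULATION_COLUMNS, "population table")


def read_standards(path) -> pd.DataFrame:
    return _read_csv_checked(path, ["copies", "ct"], "standards table")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_result_json(path, payload: dict, seed=None, config=None) -> None:
    """Write a result JSON embedding provenance (seed, config, version)."""
    from . import __version__

    out = dict(payload)
    out["_meta"] = {
        "package": "memswitch",
        "version": __version__,
        "seed": seed,
        "config": config,
        "written_at": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
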