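"""CSV/JSON/YAML readers and writers plus the run manifest.

All CSVs carry a header row, UTF-8 encoding, '.' decimal and no index
column; structured results go to JSON.  Every CLI run writes a manifest
(resolved configuration + package version + seed) next to its outputs so
any stochastic run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError

__all__ = [
    "read_ratios", "write_ratios",
    "read_calibration_pairs", "write_table",
    "read_timecourse", "read_log_intensities",
    "write_json", "read_json", "read_config", "write_manifest",
]


def _require_columns(df: pd.DataFrame, cols: set[str], path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {sorted(missing)}")


def read_ratios(path) -> np.ndarray:
    df = pd.read_csv(path)
    _require_columns(df, {"ratio"}, path)
    return df["ratio"].to_numpy(dtype=float)


def write_ratios(path, ratios) -> None:
    pd.DataFrame({"ratio": np.asarray(ratios, dtype=float)}).to_csv(path, index=False)


def read_calibration_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, {"mirna_level", "ratio"}, path)
    return df


def read_timecourse(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, {"t_divisions", "n_high", "n_total"}, path)
    return df


def read_log_intensities(path) -> np.ndarray:
    df = pd.read_csv(path)
    _require_columns(df, {"log_intensity"}, path)
    return df["log_intensity"].to_numpy(dtype=float)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n",
                          encoding="utf-8")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def read_config(path) -> dict:
    """YAML or JSON configuration file."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def write_manifest(out_dir, subcommand: str, config: dict, seed: int | None) -> Path:
    """Write the reproducibility manifest next to the outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "package_version": __version__,
        "seed": seed,
        "config": config,
    }
    path = out_dir / "manifest.json"
    write_json(path, manifest)
    return path
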