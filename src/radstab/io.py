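"""Long-format feature-table CSV I/O and fixture manifests."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synthdata import TABLE_COLUMNS

__all__ = ["read_feature_table", "write_feature_table", "read_manifest", "write_manifest"]


def write_feature_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    table[TABLE_COLUMNS].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    # round_trip parsing keeps resumed runs byte-identical
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: feature table missing columns: {missing}")
    table["subject"] = table["subject"].astype(str)
    table["value"] = table["value"].astype(float)
    return table


def write_manifest(entries: list[dict], path) -> None:
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> list[dict]:
    return json.loads(Path(path).read_text())
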