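"""End-to-end convenience: phantom fixture -> long-format feature table."""

from __future__ import annotations

import hashlib

import pandas as pd

from .radfeat import ExtractionConfig, extract_all
from .synthdata import TABLE_COLUMNS, PhantomSlot

__all__ = ["phantom_feature_table"]


def phantom_feature_table(
    slots: list[PhantomSlot], config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Extract every slot of a phantom fixture into one feature table.

    Byte-identical volumes (e.g. an identical-retest control fixture) are
    extracted once and reused — extraction is deterministic, so this is
    purely an optimization.
    """
    config = config or ExtractionConfig()
    cache: dict[bytes, dict[str, float]] = {}
    rows = []
    for s in slots:
        key = hashlib.sha1(
            s.volume.values.tobytes() + s.mask.values.tobytes()
        ).digest()
        feats = cache.get(key)
        if feats is None:
            feats = extract_all(s.volume, s.mask, config)
            cache[key] = feats
        for fid, val in feats.items():
            rows.append((s.subject, s.scanner, s.protocol.name, s.timepoint, fid, val))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
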