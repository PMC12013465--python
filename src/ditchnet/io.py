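"""Plain-text I/O: long-format abundance CSV, run configs, result tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import AbundanceTable

__all__ = [
    "write_abundance_csv",
    "read_abundance_csv",
    "write_config",
    "read_config",
]

LONG_COLUMNS = ["ditch_id", "block", "treatment_ugL", "period", "taxon", "count"]


def write_abundance_csv(table: AbundanceTable, path) -> None:
    table.to_long().to_csv(path, index=False)


def read_abundance_csv(path) -> AbundanceTable:
    """Read a long CSV (ditch_id, block, treatment_ugL, period, taxon, count)."""
    long = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in long.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    counts_raw = long["count"]
    bad = counts_raw.isna() | (counts_raw != np.floor(counts_raw.astype(float, errors="ignore")))
    if bad.any():
        row = long.index[bad][0]
        raise ValueError(f"{path}: non-integer count at row {row + 2} (taxon {long.loc[row, 'taxon']})")
    long["sample_id"] = long["ditch_id"].astype(str) + ":" + long["period"].astype(str)
    counts = long.pivot_table(index="sample_id", columns="taxon", values="count", aggfunc="sum").fillna(0).astype(int)
    counts.index.name = None
    counts.columns.name = None
    meta = (
        long.drop_duplicates("sample_id")
        .set_index("sample_id")[["ditch_id", "block", "treatment_ugL", "period"]]
    )
    meta.index.name = None
    meta = meta.loc[counts.index]
    return AbundanceTable(counts, meta)


def write_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
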