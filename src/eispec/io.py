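"""Validated CSV/TSV readers and writers for the pipeline's tidy tables.

Every table is long-format CSV with a header; writers prepend ``# key: value``
metadata comment lines (config hash, seed, package version) which readers
skip, so write -> read round-trips the declared columns exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "TableSchema",
    "SPECTRA_SCHEMA",
    "PARAMS_SCHEMA",
    "SUVR_SCHEMA",
    "BAND_SCHEMA",
    "read_table",
    "write_table",
]


class SchemaError(ValueError):
    """A table does not satisfy its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    """Declared columns, uniqueness keys and finiteness requirements."""

    name: str
    columns: tuple[str, ...]
    key: tuple[str, ...] = ()
    finite: tuple[str, ...] = ()

    def validate(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise SchemaError(f"{self.name} table is missing column(s): {missing}")
        if self.key:
            dup = df.duplicated(subset=list(self.key))
            if dup.any():
                offenders = df.loc[dup, list(self.key)].drop_duplicates().head(5)
                raise SchemaError(
                    f"{self.name} table has duplicate keys {list(self.key)}:\n{offenders}"
                )
        for c in self.finite:
            vals = pd.to_numeric(df[c], errors="coerce")
            if not np.all(np.isfinite(vals)):
                n_bad = int((~np.isfinite(vals)).sum())
                raise SchemaError(f"{self.name} table column {c!r} has {n_bad} non-finite value(s)")
        return df


SPECTRA_SCHEMA = TableSchema(
    "spectra",
    ("subject_id", "roi", "frequency_hz", "psd_db"),
    key=("subject_id", "roi", "frequency_hz"),
    finite=("frequency_hz", "psd_db"),
)
PARAMS_SCHEMA = TableSchema(
    "params",
    ("subject_id", "roi", "tau_e_ms", "tau_i_ms", "g_ee", "g_ii"),
    key=("subject_id", "roi"),
    finite=("tau_e_ms", "tau_i_ms", "g_ee", "g_ii"),
)
SUVR_SCHEMA = TableSchema(
    "suvr",
    ("subject_id", "roi", "tau_suvr", "ab_suvr"),
    key=("subject_id", "roi"),
    finite=("tau_suvr", "ab_suvr"),
)
BAND_SCHEMA = TableSchema(
    "band_power",
    ("subject_id", "roi", "band", "power_db"),
    key=("subject_id", "roi", "band"),
    finite=("power_db",),
)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV/TSV table; unknown columns are preserved."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    return schema.validate(df)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    schema: TableSchema,
    metadata: dict | None = None,
) -> Path:
    """Validate and write a table, prefixed with ``# key: value`` metadata."""
    path = Path(path)
    schema.validate(df)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep=_sep_for(path), index=False)
    return path


def config_hash(obj) -> str:
    """Stable short hash of a (dataclass-ish or dict) configuration."""
    if hasattr(obj, "__dataclass_fields__"):
        from dataclasses import asdict

        obj = asdict(obj)
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
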