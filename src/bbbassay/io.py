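"""Strict CSV schemas and provenance-carrying table I/O.

Interchange format is comma-separated UTF-8 text with '.' decimals.  Each
pipeline stage reads a named schema; required columns are coerced to their
declared types with row-addressed errors, unknown columns pass through.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

__all__ = ["SCHEMAS", "SchemaError", "load_table", "write_table", "write_provenance"]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A table does not match its declared schema."""


SCHEMAS: dict[str, dict[str, str]] = {
    "permeability": {
        "insert_id": "str", "dose_gy": "float", "day": "int", "tracer": "str",
        "cell_free": "bool", "interval_end_min": "float",
        "abluminal_conc": "float", "luminal_conc_nominal": "float",
    },
    "teer": {
        "insert_id": "str", "dose_gy": "float", "day": "int", "raw_ohm": "float",
    },
    "invivo": {
        "animal_id": "str", "age_group": "str", "region": "str",
        "dose_gy": "float", "timepoint": "str", "reading": "float",
        "tissue_mass_mg": "float", "extract_volume_ml": "float",
    },
    "standards": {"conc_ng_ml": "float", "reading": "float"},
    "counts": {
        "subject_id": "str", "dose_gy": "float", "timepoint": "str",
        "assay": "str", "numerator": "int", "denominator": "float",
    },
    "grouped": {
        "subject_id": "str", "dose_gy": "float", "timepoint": "str",
        "endpoint": "str", "value": "float",
    },
}

_CASTERS = {
    "str": lambda s: s.astype(str),
    "float": lambda s: pd.to_numeric(s, errors="raise").astype(float),
    "int": lambda s: pd.to_numeric(s, errors="raise").astype(int),
    "bool": lambda s: s.map(
        {True: True, False: False, "True": True, "False": False,
         "true": True, "false": False, 1: True, 0: False, "1": True, "0": False}
    ),
}


def load_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read a delimited text table and validate it against a named schema.

    Required columns are coerced to schema types; a missing column raises a
    :class:`SchemaError` naming it, an unparseable value an error naming the
    row.  Unknown columns are preserved untouched.
    """
    path = Path(path)
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    schema = SCHEMAS[schema_name]
    for col, typ in schema.items():
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
        try:
            coerced = _CASTERS[typ](df[col])
        except (ValueError, TypeError) as err:
            raise SchemaError(f"{path.name}: column {col!r} not {typ}: {err}") from err
        if coerced.isna().any():
            bad = int(coerced.index[coerced.isna()][0])
            raise SchemaError(
                f"{path.name}: unparseable {typ} in column {col!r} at row {bad}"
            )
        df[col] = coerced
    logger.info("loaded %s: %d rows (%s schema)", path.name, len(df), schema_name)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as deterministic CSV (no index, fixed ordering)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    logger.info("wrote %s: %d rows", path.name, len(df))
    return path


def write_provenance(meta: dict, path: str | Path) -> Path:
    """Persist the seed/parameter snapshot needed to regenerate the outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    return path
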