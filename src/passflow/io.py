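"""Delimited-table schemas, validated readers/writers and wind labelling.

Four tab-separated schemas move through the pipeline:

``trap``
    One row per taxon, date and flight direction from the bidirectional
    malaise trap: ``date, taxon, direction, count, wind_category``.
``video``
    1-min video-transect counts every 15 min over a 2 m section:
    ``timestamp, duration_min, width_m, count, sun_present``.
``visual``
    15-min visual counts of large insects over the full 30 m pass:
    ``timestamp, duration_min, width_m, taxon, count, sun_percent``.
``weather``
    Daily covariates: ``date, temp_c, wind_heading_deg, rain_mm,
    windspeed_ms, sunshine_min`` plus the derived headwind index ``h`` and
    sunshine proportion ``s`` when present.

Readers are strict: a file that violates a schema invariant raises
:class:`SchemaError` naming the offending rows, so downstream code never
sees an invalid record.  Writers emit exactly the schema columns; a
write -> read round trip is lossless for valid tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A table failed validation; the message lists offending rows."""


DIRECTIONS = ("south", "north")
WIND_CATEGORIES = ("headwind", "tailwind", "unknown")

#: schema name -> (required columns, optional columns)
SCHEMAS = {
    "trap": (["date", "taxon", "direction", "count"], ["wind_category"]),
    "video": (["timestamp", "duration_min", "width_m", "count"],
              ["sun_present"]),
    "visual": (["timestamp", "duration_min", "width_m", "taxon", "count"],
               ["sun_percent"]),
    "weather": (["date", "temp_c", "wind_heading_deg", "rain_mm",
                 "windspeed_ms", "sunshine_min"], ["h", "s"]),
}


def _fail(errors):
    raise SchemaError("; ".join(errors))


def _check_counts(df, col, errors):
    bad = df.index[(df[col] < 0) | df[col].isna()]
    for i in bad:
        errors.append(f"row {i}: {col} must be a non-negative number "
                      f"(got {df.loc[i, col]!r})")


def validate_table(df: pd.DataFrame, schema_name: str) -> pd.DataFrame:
    """Coerce types and enforce the invariants of ``schema_name``.

    Returns a typed copy; raises :class:`SchemaError` with row-indexed
    messages on any violation.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}")
    required, optional = SCHEMAS[schema_name]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema_name} table missing columns: {missing}")
    df = df.copy().reset_index(drop=True)
    errors: list = []

    if "date" in required:
        df["date"] = pd.to_datetime(df["date"], errors="coerce")
        for i in df.index[df["date"].isna()]:
            errors.append(f"row {i}: unparseable date")
        df["date"] = df["date"].dt.normalize()
    if "timestamp" in required:
        df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce")
        for i in df.index[df["timestamp"].isna()]:
            errors.append(f"row {i}: unparseable timestamp")

    if "count" in required:
        df["count"] = pd.to_numeric(df["count"], errors="coerce")
        _check_counts(df, "count", errors)
        if not errors:
            nonint = df.index[df["count"] != df["count"].round()]
            for i in nonint:
                errors.append(f"row {i}: count must be an integer")
            df["count"] = df["count"].round().astype(np.int64)

    if schema_name == "trap":
        bad = df.index[~df["direction"].isin(DIRECTIONS)]
        for i in bad:
            errors.append(f"row {i}: direction must be one of {DIRECTIONS} "
                          f"(got {df.loc[i, 'direction']!r})")
        if "wind_category" in df.columns:
            bad = df.index[~df["wind_category"].isin(WIND_CATEGORIES)]
            for i in bad:
                errors.append(f"row {i}: wind_category must be one of "
                              f"{WIND_CATEGORIES}")
    elif schema_name in ("video", "visual"):
        for col in ("duration_min", "width_m"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
            for i in df.index[(df[col] <= 0) | df[col].isna()]:
                errors.append(f"row {i}: {col} must be positive")
        if schema_name == "visual" and "sun_percent" in df.columns:
            sp = pd.to_numeric(df["sun_percent"], errors="coerce")
            for i in df.index[sp.notna() & ((sp < 0) | (sp > 100))]:
                errors.append(f"row {i}: sun_percent must lie in [0, 100]")
            df["sun_percent"] = sp
        if schema_name == "video" and "sun_present" in df.columns:
            df["sun_present"] = df["sun_present"].map(
                {True: True, False: False, "True": True, "False": False,
                 1: True, 0: False, "1": True, "0": False})
    elif schema_name == "weather":
        for col in ("temp_c", "wind_heading_deg", "rain_mm", "windspeed_ms",
                    "sunshine_min"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
            for i in df.index[df[col].isna()]:
                errors.append(f"row {i}: {col} must be numeric")
        for col in ("rain_mm", "windspeed_ms", "sunshine_min"):
            for i in df.index[df[col] < 0]:
                errors.append(f"row {i}: {col} must be non-negative")
        if "h" in df.columns:
            h = pd.to_numeric(df["h"], errors="coerce")
            for i in df.index[(h < -1 - 1e-9) | (h > 1 + 1e-9)]:
                errors.append(f"row {i}: h must lie in [-1, 1]")
        if "s" in df.columns:
            s = pd.to_numeric(df["s"], errors="coerce")
            for i in df.index[(s < 0) | (s > 1)]:
                errors.append(f"row {i}: s must lie in [0, 1]")

    if errors:
        _fail(errors)
    return df


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a tab-separated table against a named schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    return validate_table(df, schema_name)


def write_table(df: pd.DataFrame, path, schema_name: str) -> None:
    """Write the schema columns of ``df`` as a tab-separated file."""
    required, optional = SCHEMAS[schema_name]
    cols = required + [c for c in optional if c in df.columns]
    out = df[cols].copy()
    for col in ("date", "timestamp"):
        if col in out.columns:
            fmt = "%Y-%m-%d" if col == "date" else "%Y-%m-%d %H:%M"
            out[col] = pd.to_datetime(out[col]).dt.strftime(fmt)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False)


def assign_wind_category(h, threshold: float = 0.0):
    """Label days headwind/tailwind/unknown from the headwind index.

    ``h`` follows the migrants' frame: +1 is a full headwind, -1 a full
    tailwind.  Days with ``|h| <= threshold`` (the dead-band) are
    ``unknown``.  Accepts a scalar or array and returns the same shape.
    """
    h_arr = np.asarray(h, dtype=float)
    out = np.where(h_arr > threshold, "headwind",
                   np.where(h_arr < -threshold, "tailwind", "unknown"))
    if np.isscalar(h) or h_arr.ndim == 0:
        return str(out)
    return out
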