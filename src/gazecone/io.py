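"""Schema-validated CSV reading and report writing.

All trial files are RFC-4180 CSVs with a header row, UTF-8, '.' decimal
separator. Each schema lists required columns with a coercion; malformed
values are reported with their 1-based file line number (header = line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["SCHEMAS", "read_trials", "write_report"]


def _numeric(series):
    return pd.to_numeric(series, errors="coerce")


def _integer(series):
    coerced = pd.to_numeric(series, errors="coerce")
    bad = coerced.notna() & (coerced != np.floor(coerced))
    coerced[bad] = np.nan
    return coerced


def _categorical(allowed):
    def coerce(series):
        s = series.astype(str).str.strip()
        return s.where(s.isin(allowed))

    return coerce


# name -> (column -> coercion returning NaN/None for invalid cells)
SCHEMAS = {
    "dyadic_trials": {
        "observer_id": _integer,
        "trial": _integer,
        "gaze_deg": _numeric,
        "response": _categorical({"0", "1"}),
    },
    "adjustment_trials": {
        "observer_id": _integer,
        "trial": _integer,
        "series": _categorical({"ascending", "descending"}),
        "side": _categorical({"left", "right"}),
        "stop_deg": _numeric,
    },
    "triadic_trials": {
        "observer_id": _integer,
        "trial": _integer,
        "true_deg": _numeric,
        "reported_cm": _integer,
    },
}

_KEYED = {"dyadic_trials", "adjustment_trials", "triadic_trials"}


def read_trials(path, schema: str) -> pd.DataFrame:
    """Read and validate a trial CSV against a named schema.

    Raises :class:`SchemaError` naming unknown/missing columns, the file line
    of the first malformed values, or duplicate (observer_id, trial) keys.
    An empty file with a valid header yields an empty frame.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    missing = set(spec) - set(df.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {sorted(missing)}")
    unknown = set(df.columns) - set(spec)
    if unknown:
        raise SchemaError(f"{path.name}: unknown columns {sorted(unknown)}")
    if df.empty:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in spec})

    out = {}
    for col, coerce in spec.items():
        coerced = coerce(df[col])
        bad = coerced.isna().to_numpy().nonzero()[0]
        if bad.size:
            lines = [int(i) + 2 for i in bad[:5]]  # +1 header, +1 one-based
            raise SchemaError(
                f"{path.name}: invalid value(s) in column {col!r} at line(s) {lines}"
                + ("..." if bad.size > 5 else "")
            )
        out[col] = pd.to_numeric(coerced) if coerce in (_numeric, _integer) else coerced
    result = pd.DataFrame(out)
    if schema == "dyadic_trials":
        result["response"] = result["response"].astype(int)
    for col in ("observer_id", "trial", "reported_cm"):
        if col in result.columns:
            result[col] = result[col].astype(int)

    if schema in _KEYED:
        dup = result.duplicated(subset=["observer_id", "trial"])
        if dup.any():
            keys = result.loc[dup, ["observer_id", "trial"]].head(5).to_records(index=False)
            raise SchemaError(f"{path.name}: duplicate (observer_id, trial) keys, e.g. {list(keys)}")
    return result


def write_report(frame: pd.DataFrame, path, degrees_dp: int = 2, stat_dp: int = 2, p_dp: int = 3):
    """Write a summary table with presentation rounding.

    Degrees columns (suffix ``_deg``) round to ``degrees_dp``, p-values to
    ``p_dp``, other floats to ``stat_dp``; raw precision belongs in JSON, not
    in the CSV.
    """
    out = frame.copy()
    for col in out.columns:
        if not pd.api.types.is_float_dtype(out[col]):
            continue
        if col.endswith("_deg"):
            out[col] = out[col].round(degrees_dp)
        elif col.startswith("p_") or col.endswith("_p") or col == "p_value":
            out[col] = out[col].round(p_dp)
        else:
            out[col] = out[col].round(stat_dp)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path
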