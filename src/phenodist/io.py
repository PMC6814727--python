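"""CSV readers/writers for records, removal logs, LSmeans and reports."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError, SchemaError

__all__ = ["RECORD_COLUMNS", "read_records", "write_records"]

RECORD_COLUMNS = [
    "record_id",
    "household_id",
    "breed",
    "sex",
    "region",
    "lon",
    "lat",
    "week",
    "group_weight_g",
    "n_birds",
]

_NUMERIC = {"lon": float, "lat": float, "week": float, "group_weight_g": float, "n_birds": int}


def read_records(path) -> tuple[pd.DataFrame, list[dict]]:
    """Read group-weight records; collect malformed rows instead of dropping them silently.

    Returns ``(records, error_report)`` where the error report lists
    ``{"line": <1-based file line>, "error": <message>}`` for every row that
    failed type conversion.  Raises :class:`SchemaError` on a missing column
    and :class:`EmptyDatasetError` on a zero-byte/columnless file; a file
    with only a header returns an empty frame with a warning.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyDatasetError(f"{path}: file has no header or content") from None
    missing = [c for c in RECORD_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(raw) == 0:
        warnings.warn(f"{path}: header-only file, no records", stacklevel=2)
        return raw.reindex(columns=RECORD_COLUMNS), []

    errors = []
    converted = {c: raw[c] for c in RECORD_COLUMNS if c not in _NUMERIC}
    bad = np.zeros(len(raw), dtype=bool)
    for col, typ in _NUMERIC.items():
        # python float() is correctly rounded, so write->read round-trips exactly
        vals = np.empty(len(raw))
        col_bad = np.zeros(len(raw), dtype=bool)
        for i, s in enumerate(raw[col]):
            try:
                vals[i] = float(s)
            except ValueError:
                vals[i], col_bad[i] = np.nan, True
        for i in np.nonzero(col_bad & ~bad)[0]:
            errors.append({"line": int(i) + 2, "error": f"bad {col}: {raw[col].iloc[i]!r}"})
        bad |= col_bad
        converted[col] = pd.Series(vals, index=raw.index)
    df = pd.DataFrame(converted).loc[~bad].reset_index(drop=True)
    df = df[RECORD_COLUMNS]
    df["n_birds"] = df["n_birds"].astype(int)
    return df, errors


def write_records(records: pd.DataFrame, path) -> None:
    records[RECORD_COLUMNS].to_csv(path, index=False)
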