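"""Reading, validating and slicing prescription dispensation records.

The canonical in-memory container is a pandas DataFrame with columns
``client_id, physician_id, clinic_id, drug, dispense_date`` (datetime64),
sorted by (client, date, physician). ``clinic_id`` is the gold-standard
label: network construction never reads it.
"""

from __future__ import annotations

import logging

import pandas as pd

from .synthetic import DRUGS, RECORD_COLUMNS

log = logging.getLogger(__name__)

VALID_DRUGS = frozenset(DRUGS)


class RecordFormatError(ValueError):
    """Malformed prescription-record input; messages carry CSV line numbers."""


def _sorted(records: pd.DataFrame) -> pd.DataFrame:
    return records.sort_values(
        ["client_id", "dispense_date", "physician_id"], kind="mergesort"
    ).reset_index(drop=True)


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check columns, drugs and dates on an in-memory frame; return it sorted."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise RecordFormatError(f"missing columns: {missing}")
    bad_drug = ~records["drug"].astype(str).isin(VALID_DRUGS)
    if bad_drug.any():
        offending = sorted(set(records.loc[bad_drug, "drug"].astype(str)))
        raise RecordFormatError(f"unknown drug values: {offending}")
    out = records[RECORD_COLUMNS].copy()
    out["dispense_date"] = pd.to_datetime(out["dispense_date"])
    return _sorted(out)


def read_prescriptions(path, on_bad: str = "raise") -> pd.DataFrame:
    """Read a dispensation CSV with the declared header.

    Rows with a malformed date or an unknown drug are rejected: with
    ``on_bad="raise"`` (default) a :class:`RecordFormatError` reporting the
    offending CSV line numbers is raised; with ``on_bad="drop"`` they are
    logged and removed. Output is sorted by (client, date, physician).
    """
    if on_bad not in ("raise", "drop"):
        raise ValueError(f"on_bad must be 'raise' or 'drop', got {on_bad!r}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordFormatError(f"{path}: missing columns: {missing}")
    df = df[RECORD_COLUMNS]
    dates = pd.to_datetime(df["dispense_date"], format="%Y-%m-%d", errors="coerce")
    bad = dates.isna() | ~df["drug"].isin(VALID_DRUGS)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
        msg = f"{path}: {bad.sum()} malformed row(s) at line(s) {lines[:20]}"
        if on_bad == "raise":
            raise RecordFormatError(msg)
        log.warning("%s — dropped", msg)
        df = df[~bad]
        dates = dates[~bad]
    out = df.copy()
    out["dispense_date"] = dates
    return _sorted(out)


def filter_calendar_year(records: pd.DataFrame, year: int) -> pd.DataFrame:
    """Records dispensed between Jan 1 and Dec 31 of ``year`` (inclusive)."""
    years = pd.to_datetime(records["dispense_date"]).dt.year
    out = records[years == year].reset_index(drop=True)
    if out.empty:
        log.warning("no records in calendar year %d", year)
    return out
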