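"""Partial-date handling for FAERS-style YYYYMMDD / YYYYMM / YYYY fields."""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

__all__ = ["pad_partial_date", "parse_full_date", "date_to_str", "days_between"]


def pad_partial_date(value) -> int | None:
    """Right-pad a possibly partial date to the earliest full date it could mean.

    ``"2020"`` -> 20200101, ``"202003"`` -> 20200301, ``"20200315"`` -> 20200315.
    Unparseable or empty values return ``None``.  This gives a deterministic
    total order for report-retention comparisons without inventing precision.
    """
    if value is None:
        return None
    s = str(value).strip()
    if s.endswith(".0"):
        s = s[:-2]
    if not s.isdigit():
        return None
    if len(s) == 4:
        s = s + "0101"
    elif len(s) == 6:
        s = s + "01"
    elif len(s) != 8:
        return None
    year, month, day = int(s[:4]), int(s[4:6]), int(s[6:8])
    if not (1900 <= year <= 2100 and 1 <= month <= 12 and 1 <= day <= 31):
        return None
    return int(s)


def parse_full_date(value) -> _dt.date | None:
    """Parse a complete 8-digit YYYYMMDD date; partial dates return ``None``."""
    if value is None:
        return None
    s = str(value).strip()
    if s.endswith(".0"):
        s = s[:-2]
    if len(s) != 8 or not s.isdigit():
        return None
    try:
        return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None


def date_to_str(d: _dt.date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def days_between(start, end) -> float:
    """Days from ``start`` to ``end``; NaN when either date is incomplete."""
    a, b = parse_full_date(start), parse_full_date(end)
    if a is None or b is None:
        return float("nan")
    return float((b - a).days)


def pad_partial_dates(series: pd.Series) -> pd.Series:
    """Vectorised :func:`pad_partial_date`; missing -> NaN."""
    out = series.map(lambda v: pad_partial_date(v))
    return out.astype("float64").replace({None: np.nan})
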