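"""Time-to-onset analysis: latency extraction, binning, and Weibull fitting.

Latency is the number of days from the start of the suspect drug's therapy
to the event onset date.  Only reports with complete (8-digit) dates on both
ends contribute; negative intervals (event before therapy start) are excluded
and counted.  When a suspect drug has several therapy episodes, the earliest
start date is used — the conservative, longest-latency attribution.

The latency distribution is characterized by a two-parameter Weibull
MLE fit on the continuous latencies, with same-day onsets shifted to 0.5
days so the acute-onset mass is kept rather than discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._dates import parse_full_date
from .cohort import CaseSet
from .errors import InsufficientDataError

__all__ = ["LatencySummary", "WeibullFit", "compute_latencies",
           "summarize_latency", "fit_weibull", "DEFAULT_BINS"]

#: upper edges (inclusive) of the latency bins, in days; the last bin is open
DEFAULT_BINS = (30, 60, 90, 180, 365)


def compute_latencies(cases: CaseSet) -> tuple[pd.DataFrame, dict]:
    """Extract onset latencies for case reports.

    Returns ``(records, completeness)`` where ``records`` has columns
    ``primaryid``, ``onset_days``, ``drug`` and completeness counts how many
    case reports had computable intervals, incomplete dates, or negative
    intervals.
    """
    demo = cases.store.demo
    ther = cases.store.table("ther")
    drug = cases.store.table("drug")
    ps = drug[drug["role_cod"].isin(cases.definition.role_codes)]
    ps = ps[["primaryid", "drug_seq", "drugname"]]

    episodes = ther.merge(
        ps, left_on=["primaryid", "dsg_drug_seq"],
        right_on=["primaryid", "drug_seq"], how="inner")
    event = demo.set_index("primaryid")["event_dt"]

    n_cases = len(demo)
    rows, n_negative, n_incomplete = [], 0, 0
    for pid, sub in episodes.groupby("primaryid"):
        ev = parse_full_date(event.get(pid, ""))
        starts = [parse_full_date(s) for s in sub["start_dt"]]
        starts = [s for s in starts if s is not None]
        if ev is None or not starts:
            n_incomplete += 1
            continue
        start = min(starts)  # earliest episode preceding (or not) the event
        days = (ev - start).days
        if days < 0:
            n_negative += 1
            continue
        drugname = sub.iloc[0]["drugname"]
        rows.append((int(pid), int(days), drugname))

    records = pd.DataFrame(rows, columns=["primaryid", "onset_days", "drug"])
    completeness = {
        "cases": n_cases,
        "with_latency": len(records),
        "incomplete_dates": n_incomplete + (n_cases - len(records)
                                            - n_incomplete - n_negative),
        "negative_interval": n_negative,
        "completeness_fraction": len(records) / n_cases if n_cases else 0.0,
    }
    return records, completeness


def _hinge_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """Median and exclusive median-of-halves quartiles.

    The sorted sample is split at the median (which is excluded from either
    half when n is odd); Q1 and Q3 are the medians of the halves.  On
    {7, 22, 98} this yields Q1 = 7, Q3 = 98, matching how onset IQRs are
    conventionally quoted for small pharmacovigilance samples.
    """
    v = np.sort(values)
    n = len(v)
    med = float(np.median(v))
    half = n // 2
    lower = v[:half]
    upper = v[n - half:]
    q1 = float(np.median(lower)) if len(lower) else med
    q3 = float(np.median(upper)) if len(upper) else med
    return q1, med, q3


@dataclass
class LatencySummary:
    median: float
    q1: float
    q3: float
    bins: pd.DataFrame  # label, count, pct
    n: int


def summarize_latency(records: pd.DataFrame | np.ndarray,
                      bin_edges: tuple[int, ...] = DEFAULT_BINS) -> LatencySummary:
    """Median/IQR and interval-bin percentages of onset latencies."""
    days = (records["onset_days"].to_numpy()
            if isinstance(records, pd.DataFrame) else np.asarray(records))
    if len(days) == 0:
        raise InsufficientDataError("no latency records")
    q1, med, q3 = _hinge_quartiles(days.astype(float))

    edges = [0, *bin_edges]
    labels = [f"{lo + (1 if lo else 0)}–{hi}" if lo else f"0–{hi}"
              for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f">{edges[-1]}")
    counts = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        counts.append(int(((days > lo) & (days <= hi)).sum()
                          + (int((days == 0).sum()) if lo == 0 else 0)))
    counts.append(int((days > edges[-1]).sum()))
    bins = pd.DataFrame({"label": labels, "count": counts})
    bins["pct"] = 100.0 * bins["count"] / len(days)
    assert abs(bins["pct"].sum() - 100.0) < 1e-9
    return LatencySummary(median=med, q1=q1, q3=q3, bins=bins, n=len(days))


@dataclass
class WeibullFit:
    shape: float
    scale: float
    loglik: float
    n: int
    converged: bool

    @property
    def median(self) -> float:
        return self.scale * np.log(2.0) ** (1.0 / self.shape)


def fit_weibull(records: pd.DataFrame | np.ndarray,
                zero_shift: float = 0.5, min_n: int = 10) -> WeibullFit:
    """Maximum-likelihood Weibull(shape, scale) fit to onset latencies.

    Zero-day (same-day) onsets are shifted to ``zero_shift`` days so they
    stay in the likelihood.  Non-convergence and degenerate samples are
    flagged, never raised.
    """
    days = (records["onset_days"].to_numpy()
            if isinstance(records, pd.DataFrame) else np.asarray(records))
    days = days.astype(float)
    days[days == 0] = zero_shift
    days = days[days > 0]
    if len(days) < min_n:
        raise InsufficientDataError(
            f"need at least {min_n} positive latencies, got {len(days)}")
    if np.ptp(days) == 0:
        return WeibullFit(shape=float("inf"), scale=float(days[0]),
                          loglik=float("nan"), n=len(days), converged=False)
    try:
        shape, _, scale = stats.weibull_min.fit(days, floc=0)
        loglik = float(np.sum(stats.weibull_min.logpdf(days, shape, 0, scale)))
        ok = np.isfinite(loglik) and 0 < shape < 1e3 and scale > 0
    except Exception:
        shape, scale, loglik, ok = float("nan"), float("nan"), float("nan"), False
    return WeibullFit(shape=float(shape), scale=float(scale),
                      loglik=loglik, n=len(days), converged=bool(ok))
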