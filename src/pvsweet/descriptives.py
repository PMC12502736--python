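"""Cohort descriptives: demographic tables, ATC-class distributions,
stratified chi-square tests, and annual reporting trends.

Counts are always accompanied by percentages of the full universe, rounded
half-up to two decimals the way regulatory tables render them, with missing
values shown as an explicit category rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CaseSet, DrugNormalizer
from .errors import InsufficientDataError

__all__ = ["percentage", "count_table", "summarize_cohort",
           "atc_distribution", "stratified_chisq", "annual_trend", "TrendFit"]

OCCP_LABELS = {
    "MD": "Medical Doctor", "HP": "Health Professional", "CN": "Consumer",
    "PH": "Pharmacist", "LW": "Lawyer", "RN": "Registered Nurse",
    "OT": "Others",
}


def percentage(count: int, total: int, ndigits: int = 2) -> float:
    """100·count/total rounded half-up to ``ndigits`` decimals."""
    if total == 0:
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))


def count_table(values: pd.Series, total: int | None = None,
                top: int | None = None, label_map: dict | None = None,
                missing_label: str = "Missing") -> pd.DataFrame:
    """Frequency table with percentages of ``total`` and an explicit missing row.

    ``top`` keeps the most frequent levels and pools the rest as 'Others'.
    """
    s = values.fillna("").astype(str).str.strip()
    total = total if total is not None else len(s)
    missing = int((s == "").sum())
    counts = s[s != ""].value_counts()
    if label_map:
        counts.index = [label_map.get(k, k) for k in counts.index]
        counts = counts.groupby(level=0).sum().sort_values(ascending=False)
    rows = []
    if top is not None and len(counts) > top:
        head = counts.iloc[:top]
        rows += list(head.items())
        rows.append(("Others", int(counts.iloc[top:].sum())))
    else:
        rows += list(counts.items())
    if missing:
        rows.append((missing_label, missing))
    out = pd.DataFrame(rows, columns=["stratum", "count"])
    out["pct"] = [percentage(c, total) for c in out["count"]]
    return out


def _numeric_summary(values: pd.Series, total: int) -> pd.DataFrame:
    v = pd.to_numeric(values, errors="coerce")
    obs = v.dropna()
    missing = total - len(obs)
    if len(obs):
        q1, med, q3 = np.percentile(obs, [25, 50, 75])  # linear interpolation
        stats_rows = [
            ("Mean (SD)", f"{obs.mean():.2f} ({obs.std(ddof=1):.2f})"),
            ("Median [Q1, Q3]", f"{med:g} [{q1:g}, {q3:g}]"),
        ]
    else:
        stats_rows = [("Mean (SD)", ""), ("Median [Q1, Q3]", "")]
    out = pd.DataFrame(stats_rows, columns=["stratum", "value"])
    out.loc[len(out)] = ["Missing",
                         f"{missing} ({percentage(missing, total):.2f}%)"]
    return out


def summarize_cohort(cases: CaseSet) -> dict[str, pd.DataFrame]:
    """Table-1-style summaries of a case set.

    Returns sex, age, weight, reporter, country (top 6 + Others),
    indication-observed and outcome-observed tables keyed by name.
    """
    demo = cases.store.demo
    if demo.empty:
        raise InsufficientDataError("case set is empty")
    n = len(demo)
    reported = {
        "indications": cases.store.table("indi"),
        "outcomes": cases.store.table("outc"),
    }
    obs_tables = {}
    for name, t in reported.items():
        observed = demo["primaryid"].isin(t["primaryid"]).sum()
        obs_tables[name] = pd.DataFrame({
            "stratum": ["Observed", "Missing"],
            "count": [int(observed), int(n - observed)],
            "pct": [percentage(int(observed), n),
                    percentage(int(n - observed), n)],
        })
    return {
        "sex": count_table(demo["sex"].map({"M": "Male", "F": "Female"}), n),
        "age": _numeric_summary(demo["age"], n),
        "weight": _numeric_summary(demo["wt"], n),
        "reporter": count_table(demo["occp_cod"], n, label_map=OCCP_LABELS),
        "country": count_table(demo["occr_country"], n, top=6),
        "indications": obs_tables["indications"],
        "outcomes": obs_tables["outcomes"],
    }


def atc_distribution(cases: CaseSet, normalizer: DrugNormalizer | None = None,
                     level: int = 1) -> pd.DataFrame:
    """Case counts per ATC class of the suspect drug.

    A case contributes once per distinct class among its suspect drugs;
    drugs absent from the ATC map fall into an 'unclassified' row.
    Percentages are of the case-set size.
    """
    normalizer = normalizer or DrugNormalizer()
    n = cases.n_cases
    ps = cases.ps_drugs
    if ps.empty:
        return pd.DataFrame(columns=["stratum", "count", "pct"])
    idx = 0 if level == 1 else 1
    cls = ps["drug"].map(
        lambda d: (normalizer.atc(d) or ("unclassified", "unclassified"))[idx])
    per_case = pd.DataFrame({"primaryid": ps["primaryid"], "atc": cls})
    per_case = per_case.drop_duplicates()
    counts = per_case["atc"].value_counts()
    out = pd.DataFrame({"stratum": counts.index, "count": counts.values})
    out["pct"] = [percentage(int(c), n) for c in out["count"]]
    return out


def stratified_chisq(table: pd.DataFrame) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi-square (no continuity correction) on a contingency table.

    ``table`` is an r×c cross-tabulation of observed counts with meaningful
    index/column labels; missing categories must already be dropped.
    Returns (statistic, df, p, expected-count table).
    """
    obs = table.to_numpy(dtype=float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least 2 levels on each factor")
    row_margin = obs.sum(axis=1)
    col_margin = obs.sum(axis=0)
    for labels, margin, axis in ((table.index, row_margin, "row"),
                                 (table.columns, col_margin, "column")):
        zero = np.asarray(margin) == 0
        if zero.any():
            bad = list(np.asarray(labels, dtype=object)[zero])
            raise ValueError(f"degenerate table: zero {axis} margin at {bad}")
    stat, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    exp = pd.DataFrame(expected, index=table.index, columns=table.columns)
    return float(stat), int(dof), float(p), exp


def crosstab_cases(cases: CaseSet, normalizer: DrugNormalizer | None = None,
                   col: str = "sex", level: int = 1) -> pd.DataFrame:
    """ATC class × demographic factor cross-tabulation over case reports,
    dropping reports with the factor missing."""
    normalizer = normalizer or DrugNormalizer()
    demo = cases.store.demo[["primaryid", col]].copy()
    demo[col] = demo[col].fillna("").astype(str).str.strip()
    demo = demo[demo[col] != ""]
    ps = cases.ps_drugs.copy()
    idx = 0 if level == 1 else 1
    ps["atc"] = ps["drug"].map(
        lambda d: (normalizer.atc(d) or ("unclassified", "unclassified"))[idx])
    merged = ps.merge(demo, left_on="primaryid", right_on="primaryid")
    merged = merged.drop_duplicates(["primaryid", "atc"])
    return pd.crosstab(merged["atc"], merged[col])


@dataclass
class TrendFit:
    group: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    years: tuple[int, int]


def annual_trend(counts_by_year: pd.DataFrame) -> list[TrendFit]:
    """OLS of annual report count on calendar year, one fit per group.

    ``counts_by_year`` columns: ``group``, ``year``, ``count``.  Years with
    no reports inside a group's observed span count as zero.  Requires ≥3
    distinct years overall.
    """
    years = counts_by_year["year"].astype(int)
    if years.nunique() < 3:
        raise InsufficientDataError("annual trend needs at least 3 distinct years")
    lo, hi = int(years.min()), int(years.max())
    grid = np.arange(lo, hi + 1)
    fits = []
    for group, sub in counts_by_year.groupby("group"):
        y = (sub.groupby(sub["year"].astype(int))["count"].sum()
             .reindex(grid, fill_value=0).to_numpy(dtype=float))
        res = stats.linregress(grid.astype(float), y)
        fits.append(TrendFit(group=str(group), slope=float(res.slope),
                             intercept=float(res.intercept),
                             r_squared=float(res.rvalue ** 2),
                             p_value=float(res.pvalue), years=(lo, hi)))
    return fits
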