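"""Disproportionality analysis with the reporting odds ratio (ROR).

For each drug–event pair a report-level 2×2 table is formed over the
analyzed universe:

    a = reports with the drug and the event      b = drug, other events
    c = event, other drugs                       d = neither

ROR = (a/c)/(b/d) = ad/bc, with the 95% CI computed on the log scale:
exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d)).  Two-sided p-values come from
Fisher's exact test and are adjusted across the tested drug family by the
Benjamini–Hochberg false-discovery-rate step-up.  A drug is a positive
signal when it has at least ``min_cases`` reported cases and the CI lower
bound exceeds 1.

Exposure is primary-suspect only by default, and a report counts once per
cell regardless of how many rows it contributes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CaseDefinition, DrugNormalizer, case_primaryids
from .faers import ReportStore

__all__ = ["ContingencyTable", "build_table", "ror_ci", "fisher_p",
           "fdr_adjust", "screen", "screen_frames", "volcano_table"]


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # drug & event
    b: int  # drug, other events
    c: int  # event, other drugs
    d: int  # neither

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def exposure_frame(store: ReportStore, definition: CaseDefinition,
                   normalizer: DrugNormalizer) -> pd.DataFrame:
    """Distinct (primaryid, drug) exposure pairs under the definition's roles."""
    drug = store.table("drug")
    rows = drug[drug["role_cod"].isin(definition.role_codes)]
    if rows.empty:
        return pd.DataFrame(columns=["primaryid", "drug"])
    norm = normalizer.normalize_series(rows["drugname"])["drug"]
    out = pd.DataFrame({"primaryid": rows["primaryid"].astype(int), "drug": norm})
    return out.drop_duplicates().reset_index(drop=True)


def build_table(store: ReportStore, drug: str, event_pt: str | None = None,
                role_codes=frozenset({"PS"}),
                normalizer: DrugNormalizer | None = None) -> ContingencyTable:
    """Report-level 2×2 table for one drug against the rest of the universe."""
    normalizer = normalizer or DrugNormalizer()
    definition = CaseDefinition(role_codes=frozenset(role_codes))
    if event_pt is not None:
        definition = CaseDefinition(event_pt=event_pt,
                                    role_codes=frozenset(role_codes))
    cases = case_primaryids(store, definition)
    expo = exposure_frame(store, definition, normalizer)
    target = normalizer.normalize(drug)[0]
    exposed = set(expo.loc[expo["drug"] == target, "primaryid"])
    n = store.n_reports
    a = len(exposed & cases)
    b = len(exposed) - a
    c = len(cases) - a
    return ContingencyTable(a=a, b=b, c=c, d=n - a - b - c)


def ror_ci(table: ContingencyTable, alpha: float = 0.05,
           haldane: bool = False) -> tuple[float, float, float]:
    """Point estimate ad/bc and log-scale Wald CI.

    With any zero cell the estimate is undefined and (nan, nan, nan) is
    returned unless ``haldane`` adds the classical +0.5 to every cell.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0:
        return (float("nan"),) * 3
    ror = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (float(ror), float(math.exp(math.log(ror) - z * se)),
            float(math.exp(math.log(ror) + z * se)))


def fisher_p(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p: the sum, over tables with the observed
    margins, of point probabilities no larger than the observed one."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_frames(exposure: pd.DataFrame, case_ids: set[int], n_total: int,
                  drugs=None, min_cases: int = 3, strict: bool = False,
                  alpha: float = 0.05, haldane: bool = False) -> pd.DataFrame:
    """Disproportionality screen from a generic exposure frame.

    ``exposure`` holds distinct (primaryid, drug) pairs over a universe of
    ``n_total`` reports with ``case_ids`` the event-positive reports.  The
    FDR family is every tested drug with at least one case.  This is the
    single code path used for both the primary corpus and external replica
    corpora.
    """
    is_case = exposure["primaryid"].isin(case_ids)
    g = exposure.groupby("drug", sort=True)
    counts = pd.DataFrame({
        "exposed": g.size(),
        "a": is_case.groupby(exposure["drug"]).sum().astype(int),
    })
    if drugs is not None:
        drugs = [d for d in drugs]
        counts = counts.reindex(drugs).fillna(0).astype(int)
    counts = counts[counts["a"] >= 1]

    n_cases = len(case_ids)
    rows = []
    for drug, row in counts.iterrows():
        a = int(row["a"])
        b = int(row["exposed"]) - a
        c = n_cases - a
        d = n_total - a - b - c
        t = ContingencyTable(a=a, b=b, c=c, d=d)
        ror, lo, hi = ror_ci(t, alpha=alpha, haldane=haldane)
        rows.append((drug, a, b, c, d, ror, lo, hi, fisher_p(t)))
    out = pd.DataFrame(rows, columns=["drug", "a", "b", "c", "d", "ror",
                                      "ci_low", "ci_high", "p"])
    if out.empty:
        out["p_adj"] = out["signal"] = []
        return out
    out["p_adj"] = fdr_adjust(out["p"].to_numpy())
    enough = out["a"] > min_cases if strict else out["a"] >= min_cases
    out["signal"] = enough & (out["ci_low"] > 1.0)
    return out.reset_index(drop=True)


def screen(store: ReportStore, drugs=None,
           definition: CaseDefinition | None = None,
           normalizer: DrugNormalizer | None = None,
           min_cases: int = 3, strict: bool = False, alpha: float = 0.05,
           haldane: bool = False,
           reporter_filter: str | None = None) -> pd.DataFrame:
    """Screen every (or the given) drug against the target event.

    ``reporter_filter='MD'`` restricts the universe to reports submitted by
    medical doctors (OCCP_COD) before anything is counted, so subset reruns
    share the exact code path of the primary analysis.
    """
    definition = definition or CaseDefinition()
    normalizer = normalizer or DrugNormalizer()
    if reporter_filter:
        demo = store.demo
        keep = demo.loc[demo["occp_cod"].str.upper() ==
                        reporter_filter.upper(), "primaryid"]
        store = store.subset(keep.astype(int))
    expo = exposure_frame(store, definition, normalizer)
    cases = case_primaryids(store, definition)
    if drugs is not None:
        if len(drugs) == 0:
            raise ValueError("drug list must be non-empty")
        drugs = [normalizer.normalize(d)[0] for d in drugs]
    return screen_frames(expo, cases, store.n_reports, drugs=drugs,
                         min_cases=min_cases, strict=strict, alpha=alpha,
                         haldane=haldane)


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot coordinates: log2 ROR vs −log10 adjusted p, point size
    log10 case count."""
    out = results[["drug", "a", "ror", "p_adj", "signal"]].copy()
    with np.errstate(divide="ignore"):
        out["log2_ror"] = np.log2(out["ror"])
        out["neg_log10_p_adj"] = -np.log10(np.clip(out["p_adj"], 1e-300, None))
        out["log10_n"] = np.log10(out["a"])
    return out
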