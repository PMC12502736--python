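"""Case definition, drug-name normalization, indication-based exclusion
schemes, and report-level design matrices.

Cases are reports whose reactions include the target preferred term (for
Sweet's syndrome, the MedDRA PT "Sweet syndrome", code 10042458), with
exposure attributed to primary-suspect drugs only by default.  Three
predefined analytical datasets control indication-related confounding:

* ``main`` — excludes reports with malignancy-related and/or immune-related
  indications;
* ``sensitivity_A`` — excludes only malignancy-related indications;
* ``sensitivity_B`` — excludes only immune-related indications;
* ``full`` — no indication exclusion.

Reports with no indication rows are retained in every scheme: an exclusion
criterion cannot be evaluated on missing data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from . import vocab
from .errors import DegenerateDatasetError
from .faers import ReportStore

logger = logging.getLogger(__name__)

SCHEMES = ("main", "sensitivity_A", "sensitivity_B", "full")

__all__ = ["CaseDefinition", "DrugNormalizer", "IndicationClassifier",
           "CaseSet", "AnalyticalDataset", "extract_cases", "normalize_drug",
           "build_dataset", "retained_primaryids", "SCHEMES"]


@dataclass
class CaseDefinition:
    event_pt: str = vocab.TARGET_PT
    meddra_code: int = vocab.TARGET_PT_MEDDRA_CODE
    role_codes: frozenset[str] = frozenset({"PS"})

    def __post_init__(self):
        roles = frozenset(self.role_codes)
        if not roles or not roles <= {"PS", "SS", "C", "I"}:
            raise ValueError("role_codes must be a non-empty subset of "
                             "{PS, SS, C, I}")
        object.__setattr__(self, "role_codes", roles)


_WS = re.compile(r"\s+")


def _fold(name: str) -> str:
    return _WS.sub(" ", str(name).strip()).lower()


@dataclass
class DrugNormalizer:
    """Synonym-map standardization plus ATC lookup.

    Matching is deterministic and insensitive to case and surrounding
    whitespace.  Unmapped names pass through (folded) with a flag so nothing
    is silently dropped.
    """

    synonym_map: dict[str, str] = field(default_factory=vocab.default_synonym_map)
    atc_map: dict[str, tuple[str, str]] = field(default_factory=vocab.default_atc_map)

    def __post_init__(self):
        self.synonym_map = {_fold(k): v for k, v in self.synonym_map.items()}
        self.atc_map = {_fold(k): tuple(v) for k, v in self.atc_map.items()}

    def normalize(self, raw_name: str) -> tuple[str, bool]:
        """Return (standardized name, mapped flag)."""
        folded = _fold(raw_name)
        if folded in self.synonym_map:
            return self.synonym_map[folded], True
        # already-standard names count as mapped when the ATC map knows them
        return folded, folded in self.atc_map

    def normalize_series(self, names: pd.Series) -> pd.DataFrame:
        uniq = {raw: self.normalize(raw) for raw in names.dropna().unique()}
        out = names.map(lambda r: uniq.get(r, (_fold(r), False)))
        return pd.DataFrame({
            "drug": out.map(lambda t: t[0]),
            "mapped": out.map(lambda t: t[1]),
        }, index=names.index)

    def atc(self, standardized: str) -> tuple[str, str] | None:
        return self.atc_map.get(_fold(standardized))


def normalize_drug(raw_name: str, normalizer: DrugNormalizer) -> str:
    """Standardize one drug name; unmapped names pass through folded."""
    return normalizer.normalize(raw_name)[0]


@dataclass
class IndicationClassifier:
    """Flags indications as malignancy- and/or immune-related.

    The two term sets may overlap; classification returns independent flags,
    not a partition.  ``mode='substring'`` (default) matches terms anywhere
    in the reported indication PT; ``'exact'`` requires full-term equality.
    """

    malignancy_terms: list[str] = field(default_factory=vocab.default_malignancy_terms)
    immune_terms: list[str] = field(default_factory=vocab.default_immune_terms)
    mode: str = "substring"

    def __post_init__(self):
        if self.mode not in ("substring", "exact"):
            raise ValueError("mode must be 'substring' or 'exact'")
        self._mal = [t.lower() for t in self.malignancy_terms]
        self._imm = [t.lower() for t in self.immune_terms]

    def _match(self, pt: str, terms: list[str]) -> bool:
        p = str(pt).lower().strip()
        if self.mode == "exact":
            return p in terms
        return any(t in p for t in terms)

    def classify(self, indi_pt: str) -> tuple[bool, bool]:
        return (self._match(indi_pt, self._mal), self._match(indi_pt, self._imm))

    def report_flags(self, store: ReportStore) -> pd.DataFrame:
        """Per-report flags: any indication row malignancy / immune related."""
        indi = store.table("indi")
        if indi.empty:
            return pd.DataFrame(columns=["primaryid", "malignancy", "immune"])
        uniq = {pt: self.classify(pt) for pt in indi["indi_pt"].unique()}
        flags = indi[["primaryid"]].copy()
        flags["malignancy"] = indi["indi_pt"].map(lambda p: uniq[p][0])
        flags["immune"] = indi["indi_pt"].map(lambda p: uniq[p][1])
        return flags.groupby("primaryid", as_index=False).any()


@dataclass
class CaseSet:
    """Reports matching the case definition, with normalized suspect drugs."""

    store: ReportStore          # subset of the corpus: case reports only
    ps_drugs: pd.DataFrame      # primaryid, raw, drug, mapped
    definition: CaseDefinition

    @property
    def n_cases(self) -> int:
        return self.store.n_reports

    @property
    def case_ids(self) -> set[int]:
        return set(self.store.demo["primaryid"].astype(int))


def case_primaryids(store: ReportStore, definition: CaseDefinition) -> set[int]:
    reac = store.table("reac")
    if reac.empty:
        return set()
    hits = reac["pt"].str.strip().str.lower() == definition.event_pt.strip().lower()
    return set(reac.loc[hits, "primaryid"].astype(int))


def extract_cases(store: ReportStore, definition: CaseDefinition | None = None,
                  normalizer: DrugNormalizer | None = None) -> CaseSet:
    """Identify case reports by the target PT and annotate suspect drugs.

    The PT match is exact but case-insensitive.  Cases whose drug rows carry
    none of the definition's role codes are retained with zero suspect
    exposures and logged.
    """
    definition = definition or CaseDefinition()
    normalizer = normalizer or DrugNormalizer()
    ids = case_primaryids(store, definition)
    if not ids:
        logger.warning("target PT %r not found in corpus", definition.event_pt)
    case_store = store.subset(ids)
    drug = case_store.table("drug")
    ps = drug[drug["role_cod"].isin(definition.role_codes)].copy()
    if not ps.empty:
        norm = normalizer.normalize_series(ps["drugname"])
        ps_drugs = pd.DataFrame({
            "primaryid": ps["primaryid"].astype(int).values,
            "raw": ps["drugname"].values,
            "drug": norm["drug"].values,
            "mapped": norm["mapped"].values,
        }).drop_duplicates(["primaryid", "drug"]).reset_index(drop=True)
    else:
        ps_drugs = pd.DataFrame(columns=["primaryid", "raw", "drug", "mapped"])
    n_without = len(ids - set(ps_drugs["primaryid"]))
    if n_without:
        logger.info("%d case reports carry no drug with role %s",
                    n_without, sorted(definition.role_codes))
    return CaseSet(store=case_store, ps_drugs=ps_drugs, definition=definition)


def retained_primaryids(store: ReportStore, scheme: str,
                        classifier: IndicationClassifier) -> set[int]:
    """PRIMARYIDs surviving the scheme's indication exclusions."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    all_ids = set(store.demo["primaryid"].astype(int))
    if scheme == "full":
        return all_ids
    flags = classifier.report_flags(store)
    if flags.empty:
        return all_ids
    if scheme == "main":
        drop = flags.loc[flags["malignancy"] | flags["immune"], "primaryid"]
    elif scheme == "sensitivity_A":
        drop = flags.loc[flags["malignancy"], "primaryid"]
    else:  # sensitivity_B
        drop = flags.loc[flags["immune"], "primaryid"]
    return all_ids - set(drop.astype(int))


@dataclass
class AnalyticalDataset:
    """Report-level design matrix under one exclusion scheme.

    ``frame`` has one row per retained report: ``case`` (0/1), ``age``
    (years, NaN if missing), ``sex`` ('M'/'F'/''), and one 0/1 exposure
    indicator per candidate drug (primary-suspect exposure only).
    """

    scheme: str
    frame: pd.DataFrame
    candidate_drugs: list[str]
    provenance: dict[str, int]

    @property
    def n_cases(self) -> int:
        return int(self.frame["case"].sum())

    @property
    def retained_primaryids(self) -> set[int]:
        return set(self.frame["primaryid"].astype(int))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def build_dataset(store: ReportStore, scheme: str, candidate_drugs: list[str],
                  definition: CaseDefinition | None = None,
                  normalizer: DrugNormalizer | None = None,
                  classifier: IndicationClassifier | None = None,
                  ) -> AnalyticalDataset:
    """Assemble the design matrix for one exclusion scheme."""
    if not candidate_drugs:
        raise ValueError("candidate_drugs must be non-empty")
    definition = definition or CaseDefinition()
    normalizer = normalizer or DrugNormalizer()
    classifier = classifier or IndicationClassifier()

    all_ids = set(store.demo["primaryid"].astype(int))
    retained = retained_primaryids(store, scheme, classifier)
    if not retained:
        raise DegenerateDatasetError(
            f"scheme {scheme!r} excluded every report")

    demo = store.demo
    keep = demo["primaryid"].astype(int).isin(retained)
    frame = demo.loc[keep, ["primaryid", "age", "sex"]].copy()
    frame["primaryid"] = frame["primaryid"].astype(int)

    cases = case_primaryids(store, definition)
    frame.insert(1, "case", frame["primaryid"].isin(cases).astype(int))

    drug = store.table("drug")
    ps = drug[drug["role_cod"].isin(definition.role_codes)]
    norm = normalizer.normalize_series(ps["drugname"])["drug"]
    expo = pd.DataFrame({"primaryid": ps["primaryid"].astype(int), "drug": norm})
    expo = expo[expo["drug"].isin(candidate_drugs)].drop_duplicates()
    wide = pd.crosstab(expo["primaryid"], expo["drug"]).clip(upper=1)
    for d in candidate_drugs:
        frame[d] = frame["primaryid"].map(
            wide[d] if d in wide.columns else pd.Series(dtype=int)).fillna(0).astype(int)

    provenance = {
        "input_reports": len(all_ids),
        "excluded_by_indication": len(all_ids) - len(retained),
        "retained": len(retained),
        "cases_retained": int(frame["case"].sum()),
    }
    return AnalyticalDataset(scheme=scheme, frame=frame.reset_index(drop=True),
                             candidate_drugs=list(candidate_drugs),
                             provenance=provenance)
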