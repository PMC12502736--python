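"""Cross-database replication and the three-source evidence matrix.

The disproportionality screen is replicated verbatim on a second corpus
supplied in a minimal normalized schema — ``report_id``, ``drug``, ``role``,
``pt`` — one row per drug or reaction entry (this is the shape a VigiBase
or other licensed extract is reduced to by its owner; no proprietary format
is parsed here).  The external signal rule matches the primary one: at
least three reported cases and an ROR 95% CI lower bound above 1.

Literature support and product-label listings are manual review products and
enter only as a curated annotations TSV with columns ``drug``,
``literature`` (0/1), ``citations``, ``label`` (0/1), ``label_source``.
"""

from __future__ import annotations

import logging

import pandas as pd

from .cohort import DrugNormalizer
from .errors import MappingError
from .signals import screen_frames

logger = logging.getLogger(__name__)

__all__ = ["replicate_screen", "assemble_matrix", "read_external_corpus",
           "read_annotations", "EXTERNAL_COLUMNS"]

EXTERNAL_COLUMNS = ("report_id", "drug", "role", "pt")


def read_external_corpus(path_or_frame) -> pd.DataFrame:
    """Load and validate the minimal external-corpus schema."""
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame, sep="\t", dtype=str,
                         keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in EXTERNAL_COLUMNS if c not in df.columns]
    if missing:
        raise MappingError(
            f"external corpus is missing required columns: {missing}")
    return df


def replicate_screen(external, drugs=None, event_pt: str = "Sweet syndrome",
                     role_codes=frozenset({"PS"}),
                     normalizer: DrugNormalizer | None = None,
                     min_cases: int = 3, strict: bool = False,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Run the primary disproportionality screen on an external corpus.

    The universe is every distinct report id; exposure, case definition,
    ROR/CI/Fisher/FDR and the signal rule reuse :mod:`pvsweet.signals`
    unchanged, so nothing database-specific leaks into the statistics.
    """
    normalizer = normalizer or DrugNormalizer()
    df = read_external_corpus(external)
    n_total = df["report_id"].nunique()
    drug_rows = df[df["drug"].astype(str).str.strip() != ""]
    drug_rows = drug_rows[drug_rows["role"].isin(set(role_codes))]
    norm = normalizer.normalize_series(drug_rows["drug"])["drug"]
    exposure = pd.DataFrame({"primaryid": drug_rows["report_id"],
                             "drug": norm}).drop_duplicates()
    cases = set(df.loc[df["pt"].str.strip().str.lower()
                       == event_pt.strip().lower(), "report_id"])
    if drugs is not None:
        drugs = [normalizer.normalize(d)[0] for d in drugs]
    return screen_frames(exposure, cases, n_total, drugs=drugs,
                         min_cases=min_cases, strict=strict, alpha=alpha)


def read_annotations(path_or_frame) -> pd.DataFrame:
    if isinstance(path_or_frame, pd.DataFrame):
        ann = path_or_frame.copy()
    else:
        ann = pd.read_csv(path_or_frame, sep="\t", dtype=str,
                          keep_default_na=False)
    ann.columns = [c.strip().lower() for c in ann.columns]
    if "drug" not in ann.columns:
        raise MappingError("annotations file needs a 'drug' column")
    for col, default in (("literature", "0"), ("citations", ""),
                         ("label", "0"), ("label_source", "")):
        if col not in ann.columns:
            ann[col] = default
    return ann


def assemble_matrix(faers_signals: pd.DataFrame,
                    external_signals: pd.DataFrame | None = None,
                    annotations: pd.DataFrame | None = None,
                    drugs: list[str] | None = None) -> pd.DataFrame:
    """Structured evidence matrix for the main-analysis drugs.

    One row per drug with flags from each source: the primary
    disproportionality signal, the external replication (with its n, ROR,
    CI), literature support and product-label listing from the annotations
    file.  Annotation rows for drugs outside the main list are skipped with
    a warning.
    """
    if drugs is None:
        drugs = list(faers_signals["drug"])
    base = faers_signals.set_index("drug")
    matrix = pd.DataFrame({"drug": drugs}).set_index("drug")
    matrix["faers_signal"] = base["signal"].reindex(matrix.index).fillna(False)

    matrix["external_signal"] = False
    matrix["external_n"] = 0
    matrix["external_ror"] = float("nan")
    matrix["external_ci_low"] = float("nan")
    if external_signals is not None and not external_signals.empty:
        ext = external_signals.set_index("drug")
        common = matrix.index.intersection(ext.index)
        matrix.loc[common, "external_signal"] = ext.loc[common, "signal"]
        matrix.loc[common, "external_n"] = ext.loc[common, "a"]
        matrix.loc[common, "external_ror"] = ext.loc[common, "ror"]
        matrix.loc[common, "external_ci_low"] = ext.loc[common, "ci_low"]

    matrix["literature_support"] = False
    matrix["citations"] = ""
    matrix["label_listed"] = False
    matrix["label_source"] = ""
    if annotations is not None:
        ann = read_annotations(annotations)
        for _, row in ann.iterrows():
            d = str(row["drug"]).strip().lower()
            if d not in matrix.index:
                logger.warning("annotation drug %r not in main list; skipped", d)
                continue
            matrix.loc[d, "literature_support"] = str(row["literature"]).strip() in ("1", "true", "True")
            matrix.loc[d, "citations"] = row["citations"]
            matrix.loc[d, "label_listed"] = str(row["label"]).strip() in ("1", "true", "True")
            matrix.loc[d, "label_source"] = row["label_source"]

    matrix = matrix.reset_index()
    matrix.attrs["overlap_counts"] = {
        "drugs": len(matrix),
        "external_signal": int(matrix["external_signal"].sum()),
        "literature_support": int(matrix["literature_support"].sum()),
        "label_listed": int(matrix["label_listed"].sum()),
    }
    return matrix
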