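"""Reading FAERS-style quarterly ASCII extracts and report deduplication.

The seven relational tables arrive as $-delimited text with one header row.
Headers drifted across quarters (e.g. ``GNDR_COD`` for sex in early years);
:mod:`pvsweet.schema` maps known aliases onto a canonical lowercase schema and
passes unknown columns through untouched.

Deduplication follows the FDA retention rule for spontaneous reports: among
records sharing a CASEID, keep the one with the most recent FDA receipt date
(FDA_DT); if receipt dates tie, keep the highest PRIMARYID.  Partial receipt
dates are compared after right-padding to the earliest date they could
denote (YYYY -> YYYY0101), which yields a deterministic order without
inventing precision.
"""

from __future__ import annotations

import csv
import glob as _glob
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import schema
from ._dates import pad_partial_date
from .errors import IntegrityError, SchemaError

logger = logging.getLogger(__name__)

__all__ = ["ReportStore", "DedupLedger", "read_quarters", "deduplicate",
           "save_store", "load_store"]


@dataclass
class ReportStore:
    """Canonical in-memory corpus: one DataFrame per relational table."""

    tables: dict[str, pd.DataFrame]
    quarters: list[str] = field(default_factory=list)
    raw_counts: dict[str, int] = field(default_factory=dict)

    @property
    def demo(self) -> pd.DataFrame:
        return self.tables["demo"]

    def table(self, name: str) -> pd.DataFrame:
        return self.tables.get(name, schema.empty_table(name))

    @property
    def n_reports(self) -> int:
        return len(self.tables["demo"])

    def subset(self, primaryids) -> "ReportStore":
        """Restrict every table to the given PRIMARYIDs."""
        ids = pd.Series(sorted(set(primaryids)), dtype="Int64")
        out = {}
        for name, df in self.tables.items():
            out[name] = df[df["primaryid"].isin(ids)].reset_index(drop=True)
        return ReportStore(tables=out, quarters=list(self.quarters),
                           raw_counts=dict(self.raw_counts))


@dataclass
class DedupLedger:
    """Record of the retention decision for every input DEMO row."""

    kept: set[int]
    dropped: list[tuple[int, str]]  # (primaryid, 'older_fda_dt'|'lower_primaryid')
    no_caseid: int = 0

    def summary(self) -> dict:
        reasons = pd.Series([r for _, r in self.dropped], dtype=object)
        return {
            "kept": len(self.kept),
            "dropped": len(self.dropped),
            "no_caseid_kept_as_singletons": self.no_caseid,
            "dropped_by_reason": reasons.value_counts().to_dict(),
        }


_PREFIXES = {"DEMO": "demo", "DRUG": "drug", "REAC": "reac", "OUTC": "outc",
             "RPSR": "rpsr", "THER": "ther", "INDI": "indi"}


def _table_of(path: str) -> str | None:
    base = os.path.basename(path).upper()
    for prefix, name in _PREFIXES.items():
        if base.startswith(prefix):
            return name
    return None


def _read_ascii(path: str, bad_rows: list) -> pd.DataFrame:
    def _on_bad(row):
        bad_rows.append(row)
        return None

    kwargs = dict(sep="$", dtype=str, keep_default_na=False,
                  quoting=csv.QUOTE_NONE, escapechar="\\",
                  engine="python", on_bad_lines=_on_bad)
    try:
        return pd.read_csv(path, encoding="utf-8", **kwargs)
    except UnicodeDecodeError:
        # FAERS files mix encodings; latin-1 accepts any byte stream
        return pd.read_csv(path, encoding="latin-1", **kwargs)


def read_quarters(paths, malformed_tolerance: float = 0.01) -> ReportStore:
    """Read quarterly ASCII files/directories into one canonical store.

    ``paths`` may mix directories (scanned for ``DEMO*.txt`` etc.), glob
    patterns and individual files.  Malformed rows (wrong field count) are
    counted and logged; a per-file fraction above ``malformed_tolerance``
    raises :class:`IntegrityError`.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    files: list[str] = []
    for p in paths:
        p = str(p)
        if os.path.isdir(p):
            files.extend(sorted(_glob.glob(os.path.join(p, "*.txt")))
                         + sorted(_glob.glob(os.path.join(p, "*.TXT"))))
        elif any(ch in p for ch in "*?["):
            files.extend(sorted(_glob.glob(p)))
        elif os.path.exists(p):
            files.append(p)
        else:
            raise FileNotFoundError(p)

    frames: dict[str, list[pd.DataFrame]] = {t: [] for t in schema.TABLES}
    quarters: list[str] = []
    for path in files:
        table = _table_of(path)
        if table is None:
            logger.warning("skipping unrecognized file %s", path)
            continue
        bad: list = []
        df = _read_ascii(path, bad)
        if bad:
            frac = len(bad) / max(len(df) + len(bad), 1)
            logger.warning("%s: %d malformed rows (%.2f%%)", path, len(bad),
                           100 * frac)
            if frac > malformed_tolerance:
                raise IntegrityError(
                    f"{path}: malformed-row fraction {frac:.3f} exceeds "
                    f"tolerance {malformed_tolerance}")
        df = schema.canonicalize_columns(df)
        for col in schema.MANDATORY.get(table, []):
            if col not in df.columns:
                raise SchemaError(f"{path}: mandatory column {col!r} missing")
        frames[table].append(schema.coerce_types(df, table))
        quarter = os.path.basename(path)
        quarter = quarter[4:].rsplit(".", 1)[0]
        if quarter and quarter not in quarters:
            quarters.append(quarter)

    tables = {}
    raw_counts = {}
    for name in schema.TABLES:
        if frames[name]:
            tables[name] = pd.concat(frames[name], ignore_index=True)
        else:
            tables[name] = schema.empty_table(name)
        raw_counts[name] = len(tables[name])
    if tables["demo"].empty and raw_counts["demo"] == 0 and not files:
        raise SchemaError("no input files found")
    return ReportStore(tables=tables, quarters=quarters, raw_counts=raw_counts)


def deduplicate(store: ReportStore) -> tuple[ReportStore, DedupLedger]:
    """Apply the FDA retention rule; returns the reduced store and a ledger.

    Idempotent and order-independent: the kept set depends only on
    (CASEID, padded FDA_DT, PRIMARYID) triples.  Reports without a CASEID
    are kept as singletons and counted.
    """
    demo = store.demo
    if demo.empty:
        return store, DedupLedger(kept=set(), dropped=[])

    work = demo[["primaryid", "caseid", "fda_dt"]].copy()
    work["_fda_key"] = work["fda_dt"].map(
        lambda v: pad_partial_date(v) if str(v).strip() else None)
    work["_fda_key"] = pd.to_numeric(work["_fda_key"], errors="coerce").fillna(-1)

    no_case = work["caseid"].isna()
    kept_ids = set(work.loc[no_case, "primaryid"].astype(int))
    n_no_case = int(no_case.sum())
    if n_no_case:
        logger.info("%d reports without CASEID kept as singletons", n_no_case)

    dropped: list[tuple[int, str]] = []
    grouped = work[~no_case].sort_values(
        ["caseid", "_fda_key", "primaryid"], kind="stable")
    winners = grouped.groupby("caseid", sort=False).tail(1)
    kept_ids.update(winners["primaryid"].astype(int))
    win_key = winners.set_index("caseid")["_fda_key"]
    losers = grouped[~grouped["primaryid"].isin(winners["primaryid"])]
    for pid, cid, key in zip(losers["primaryid"], losers["caseid"],
                             losers["_fda_key"]):
        reason = "older_fda_dt" if key < win_key[cid] else "lower_primaryid"
        dropped.append((int(pid), reason))

    ledger = DedupLedger(kept=kept_ids, dropped=dropped, no_caseid=n_no_case)
    return store.subset(kept_ids), ledger


def save_store(store: ReportStore, directory) -> None:
    """Serialize a store to a columnar cache (parquet, one file per table)."""
    os.makedirs(directory, exist_ok=True)
    for name, df in store.tables.items():
        df.to_parquet(os.path.join(directory, f"{name}.parquet"))


def load_store(directory) -> ReportStore:
    tables = {}
    for name in schema.TABLES:
        path = os.path.join(directory, f"{name}.parquet")
        tables[name] = (pd.read_parquet(path) if os.path.exists(path)
                        else schema.empty_table(name))
    return ReportStore(tables=tables)
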