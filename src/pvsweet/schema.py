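"""Canonical table schema for FAERS-style spontaneous-report corpora.

Seven relational tables keyed by PRIMARYID: demographics (DEMO), drugs
(DRUG), reactions (REAC), outcomes (OUTC), report sources (RPSR), therapy
dates (THER) and indications (INDI).  Quarterly extracts have drifted in
their header spelling over the years; readers map any known alias onto the
canonical lowercase names below and keep unknown columns untouched.
"""

from __future__ import annotations

import pandas as pd

TABLES = ("demo", "drug", "reac", "outc", "rpsr", "ther", "indi")

#: canonical column order per table
CANONICAL_COLUMNS: dict[str, list[str]] = {
    "demo": [
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "sex", "wt",
        "occp_cod", "occr_country",
    ],
    "drug": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    "reac": ["primaryid", "caseid", "pt"],
    "outc": ["primaryid", "caseid", "outc_cod"],
    "rpsr": ["primaryid", "caseid", "rpsr_cod"],
    "ther": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
    "indi": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
}

#: alias -> canonical, applied case-insensitively.  GNDR_COD is the pre-2014
#: spelling of SEX; REPORTER_COUNTRY appears in some eras alongside
#: OCCR_COUNTRY.  Users may extend this map for older (ISR-era) files.
COLUMN_ALIASES: dict[str, str] = {
    "gndr_cod": "sex",
    "reporter_country": "occr_country",
    "indi_pt": "indi_pt",
    "drugname": "drugname",
}

#: columns parsed as integers (nullable) / floats; everything else is text
INT_COLUMNS = {"primaryid", "caseid", "drug_seq", "dsg_drug_seq", "indi_drug_seq"}
FLOAT_COLUMNS = {"age", "wt"}
DATE_COLUMNS = {"fda_dt", "event_dt", "start_dt", "end_dt"}

#: FAERS role codes: primary suspect, secondary suspect, concomitant, interacting
ROLE_CODES = ("PS", "SS", "C", "I")

MANDATORY = {"demo": ["primaryid", "caseid"]}


def canonicalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Lower-case known headers and apply the alias map; unknown columns keep
    their original names."""
    rename = {}
    known = set().union(*CANONICAL_COLUMNS.values())
    for col in df.columns:
        low = col.strip().lower()
        if low in COLUMN_ALIASES:
            rename[col] = COLUMN_ALIASES[low]
        elif low in known:
            rename[col] = low
    return df.rename(columns=rename)


def coerce_types(df: pd.DataFrame, table: str) -> pd.DataFrame:
    """Coerce canonical columns to their working dtypes.

    Identifiers become nullable integers, age/weight floats, and dates stay
    as text so partial dates (YYYYMM, YYYY) survive untouched.
    """
    df = df.copy()
    for col in df.columns:
        if col in INT_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
        elif col in FLOAT_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("float64")
        elif col in DATE_COLUMNS or df[col].dtype == object:
            df[col] = df[col].fillna("").astype(str).str.strip()
            df[col] = df[col].replace({"nan": "", "None": "", "<NA>": ""})
    return df


def empty_table(table: str) -> pd.DataFrame:
    return coerce_types(pd.DataFrame(columns=CANONICAL_COLUMNS[table]), table)
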