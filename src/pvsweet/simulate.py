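"""Synthetic FAERS-style report generator with planted drug–event signals.

Builds multi-table spontaneous-report corpora shaped like quarterly FAERS
ASCII extracts: demographics with realistic missingness, drug rows with role
codes and free-text name variants, reaction preferred terms including a rare
target event, indications drawn from malignancy / immune / other pools,
therapy dates with Weibull-distributed onset latencies, and duplicate CASEIDs
cloned under later receipt dates.

The planted effect size is specified on the odds-ratio scale against the
pooled comparator — the same estimand the reporting odds ratio measures — by
tilting the event probability for exposed reports:

    odds(event | drug) = multiplier × odds(event | pooled comparator of drug)

Because the comparator pool itself contains the other (possibly elevated)
drugs, the exposed-event probabilities are calibrated by a short fixed-point
iteration so each planted drug's odds ratio against its own comparator —
the quantity the reporting odds ratio estimates — equals the configured
multiplier.  Unplanted drugs keep the background event rate.
"""

from __future__ import annotations

import csv
import dataclasses
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import schema, vocab
from .errors import ConfigurationError

__all__ = ["SimulationConfig", "SyntheticCorpus", "generate_corpus",
           "write_faers_ascii", "default_config"]

_EPOCH = np.datetime64("2004-01-01")
_HORIZON_DAYS = 7000  # therapy starts drawn from the first ~19 years


def _default_missingness() -> dict[str, float]:
    # Demographic rates follow large published FAERS cohorts of this event
    # (age ~22.6%, weight ~84.5%, sex ~10.3% missing); date completeness is
    # set so roughly a quarter of cases carry a computable time-to-onset.
    return {
        "age": 0.226,
        "wt": 0.845,
        "sex": 0.103,
        "occp_cod": 0.046,
        "occr_country": 0.030,
        "event_dt": 0.35,
        "start_dt": 0.55,
        "indication": 0.0634,
    }


@dataclass
class SimulationConfig:
    """Parameters of one synthetic corpus.

    ``drug_catalog`` rows are ``(name, atc_level1, atc_level2, pool)`` where
    ``pool`` tags the indication pool the drug's reports draw from
    (``malignancy`` / ``immune`` / ``other``).  ``planted_signals`` maps drug
    name -> true reporting odds ratio multiplier (1.0 = null).
    """

    n_reports: int = 20_000
    target_pt: str = vocab.TARGET_PT
    background_event_rate: float = 0.005
    drug_catalog: list[tuple[str, str, str, str]] = field(
        default_factory=lambda: list(vocab.DEFAULT_CATALOG))
    planted_signals: dict[str, float] = field(default_factory=dict)
    duplicate_fraction: float = 0.0
    missingness: dict[str, float] = field(default_factory=_default_missingness)
    tto_weibull: tuple[float, float] = (0.9, 40.0)
    reporter_mix: dict[str, float] = field(
        default_factory=lambda: dict(vocab.REPORTER_MIX))
    partial_date_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ConfigurationError("n_reports must be a positive integer")
        if not (0.0 < self.background_event_rate < 1.0):
            raise ConfigurationError("background_event_rate must lie in (0, 1)")
        if not (0.0 <= self.duplicate_fraction < 1.0):
            raise ConfigurationError("duplicate_fraction must lie in [0, 1)")
        if not (0.0 <= self.partial_date_fraction <= 1.0):
            raise ConfigurationError("partial_date_fraction must lie in [0, 1]")
        if not self.drug_catalog:
            raise ConfigurationError("drug_catalog must be non-empty")
        names = {d[0] for d in self.drug_catalog}
        if len(names) != len(self.drug_catalog):
            raise ConfigurationError("drug_catalog contains duplicate names")
        for drug, mult in self.planted_signals.items():
            if drug not in names:
                raise ConfigurationError(
                    f"planted_signals: drug {drug!r} not in drug_catalog")
            if not mult > 0:
                raise ConfigurationError(
                    f"planted_signals: multiplier for {drug!r} must be > 0")
        for fld, p in self.missingness.items():
            if not (0.0 <= p < 1.0):
                raise ConfigurationError(
                    f"missingness: probability for {fld!r} must lie in [0, 1)")
        shape, scale = self.tto_weibull
        if not (shape > 0 and scale > 0):
            raise ConfigurationError("tto_weibull: shape and scale must be > 0")
        total = sum(self.reporter_mix.values())
        if self.reporter_mix and abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"reporter_mix weights sum to {total!r}, expected 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                kwargs[f.name] = raw[f.name]
        if "drug_catalog" in kwargs:
            kwargs["drug_catalog"] = [tuple(row) for row in kwargs["drug_catalog"]]
        if "tto_weibull" in kwargs:
            kwargs["tto_weibull"] = tuple(kwargs["tto_weibull"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class SyntheticCorpus:
    """Seven canonical tables plus the generating truth."""

    tables: dict[str, pd.DataFrame]
    truth: dict[str, float]
    seed_used: int
    config: SimulationConfig | None = None

    @property
    def demo(self) -> pd.DataFrame:
        return self.tables["demo"]


def default_config(**overrides) -> SimulationConfig:
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


def _dates_to_str(days: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Day offsets from the 2004 epoch -> YYYYMMDD strings ('' if missing)."""
    dt = _EPOCH + days.astype("timedelta64[D]")
    out = np.datetime_as_string(dt, unit="D")
    out = np.char.replace(out, "-", "")
    out[missing] = ""
    return out


def _degrade_partial(dates: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Truncate a fraction of full dates to YYYYMM or YYYY precision."""
    if frac <= 0:
        return dates
    full = np.array([len(s) == 8 for s in dates])
    hit = full & (rng.random(len(dates)) < frac)
    to_month = hit & (rng.random(len(dates)) < 0.5)
    to_year = hit & ~to_month
    out = dates.copy()
    out[to_month] = [s[:6] for s in out[to_month]]
    out[to_year] = [s[:4] for s in out[to_year]]
    return out


def generate_corpus(config: SimulationConfig) -> SyntheticCorpus:
    """Generate one corpus; deterministic for a given config + seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    catalog = config.drug_catalog
    n_drugs = len(catalog)
    drug_names = np.array([d[0] for d in catalog])
    pool_tags = np.array([d[3] for d in catalog])

    caseid = 10_000_000 + np.arange(n, dtype=np.int64)
    primaryid = caseid * 10 + 1

    # --- exposure and outcome -------------------------------------------
    ps_idx = rng.integers(0, n_drugs, n)
    mult = np.ones(n_drugs)
    planted_mask = np.zeros(n_drugs, dtype=bool)
    for drug, m in config.planted_signals.items():
        j = np.where(drug_names == drug)[0][0]
        mult[j] = m
        planted_mask[j] = True
    p0 = config.background_event_rate
    # calibrate planted event probabilities so each drug's odds ratio against
    # its pooled comparator equals the configured multiplier (exposure is
    # uniform over the catalog, so comparator odds use unweighted sums)
    p = np.full(n_drugs, p0)
    odds0 = p0 / (1.0 - p0)
    p[planted_mask] = (mult * odds0 / (1 + mult * odds0))[planted_mask]
    for _ in range(200):
        comparator_odds = (p.sum() - p) / ((1.0 - p).sum() - (1.0 - p))
        odds_new = mult * comparator_odds
        p_new = np.where(planted_mask, odds_new / (1.0 + odds_new), p)
        if np.max(np.abs(p_new - p)) < 1e-14:
            p = p_new
            break
        p = p_new
    p_event = p[ps_idx]
    is_case = rng.random(n) < p_event

    # --- dates -----------------------------------------------------------
    start_day = rng.integers(0, _HORIZON_DAYS, n)
    shape, scale = config.tto_weibull
    latency = np.where(
        is_case,
        np.round(scale * rng.weibull(shape, n)),
        np.round(rng.uniform(0, 365, n)),
    ).astype(np.int64)
    event_day = start_day + latency
    fda_day = event_day + rng.integers(0, 90, n)

    # --- demographics ----------------------------------------------------
    age = np.clip(np.round(rng.normal(55, 18, n)), 1, 100)
    wt = np.clip(np.round(rng.normal(73, 20, n), 1), 30, 200)
    sex = rng.choice(np.array(["M", "F"]), n, p=[0.43, 0.57])
    occp = rng.choice(np.array(list(config.reporter_mix)), n,
                      p=np.array(list(config.reporter_mix.values())))
    country = rng.choice(np.array(vocab.COUNTRIES), n, p=vocab.COUNTRY_WEIGHTS)

    miss = {f: rng.random(n) < p for f, p in config.missingness.items()}
    nomiss = np.zeros(n, dtype=bool)

    age = age.astype(float)
    age[miss.get("age", nomiss)] = np.nan
    wt = wt.astype(float)
    wt[miss.get("wt", nomiss)] = np.nan
    sex[miss.get("sex", nomiss)] = ""
    occp[miss.get("occp_cod", nomiss)] = ""
    country[miss.get("occr_country", nomiss)] = ""

    event_dt = _dates_to_str(event_day, miss.get("event_dt", nomiss))
    start_dt = _dates_to_str(start_day, miss.get("start_dt", nomiss))
    fda_dt = _dates_to_str(fda_day, nomiss)
    event_dt = _degrade_partial(event_dt, config.partial_date_fraction, rng)
    start_dt = _degrade_partial(start_dt, config.partial_date_fraction, rng)

    demo = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "fda_dt": fda_dt,
        "event_dt": event_dt, "age": age, "sex": sex, "wt": wt,
        "occp_cod": occp, "occr_country": country,
    })

    # --- drug rows: one primary suspect + 0–4 concomitants ---------------
    ps = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid,
        "drug_seq": np.ones(n, dtype=np.int64),
        "role_cod": "PS", "drugname": drug_names[ps_idx],
    })
    n_con = rng.integers(0, 5, n)
    rep = np.repeat(np.arange(n), n_con)
    con_idx = rng.integers(0, n_drugs, rep.size)
    keep = con_idx != ps_idx[rep]
    rep, con_idx = rep[keep], con_idx[keep]
    con = pd.DataFrame({
        "primaryid": primaryid[rep], "caseid": caseid[rep],
        "drug_seq": np.zeros(rep.size, dtype=np.int64),
        "role_cod": "C", "drugname": drug_names[con_idx],
    })
    con = con.drop_duplicates(["primaryid", "drugname"])
    con["drug_seq"] = con.groupby("primaryid").cumcount() + 2
    drug = pd.concat([ps, con], ignore_index=True)
    drug = drug.sort_values(["primaryid", "drug_seq"], kind="stable",
                            ignore_index=True)

    # --- reactions --------------------------------------------------------
    n_extra = np.where(is_case, rng.integers(0, 3, n), rng.integers(1, 4, n))
    rep_r = np.repeat(np.arange(n), n_extra)
    extra_pt = rng.choice(np.array(vocab.BACKGROUND_PTS), rep_r.size)
    reac = pd.concat([
        pd.DataFrame({"primaryid": primaryid[is_case],
                      "caseid": caseid[is_case], "pt": config.target_pt}),
        pd.DataFrame({"primaryid": primaryid[rep_r], "caseid": caseid[rep_r],
                      "pt": extra_pt}),
    ], ignore_index=True)
    reac = reac.drop_duplicates(["primaryid", "pt"])
    reac = reac.sort_values(["primaryid", "pt"], kind="stable", ignore_index=True)

    # --- indications for the primary suspect -----------------------------
    has_indi = ~miss.get("indication", nomiss)
    pool_of_report = pool_tags[ps_idx]
    own_pool = rng.random(n) < 0.8
    indi_terms = np.empty(n, dtype=object)
    for tag, terms in vocab.INDICATION_POOLS.items():
        sel = pool_of_report == tag
        indi_terms[sel] = rng.choice(np.array(terms), int(sel.sum())) if sel.any() else None
    other_terms = np.array(vocab.INDICATION_POOLS["other"])
    fallback = ~own_pool & (pool_of_report != "other")
    if fallback.any():
        indi_terms[fallback] = rng.choice(other_terms, int(fallback.sum()))
    indi = pd.DataFrame({
        "primaryid": primaryid[has_indi], "caseid": caseid[has_indi],
        "indi_drug_seq": 1, "indi_pt": indi_terms[has_indi],
    })

    # --- therapy dates for the primary suspect ---------------------------
    ther = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "dsg_drug_seq": 1,
        "start_dt": start_dt, "end_dt": "",
    })

    # --- outcomes and report sources --------------------------------------
    has_outc = rng.random(n) < 0.9856
    outc = pd.DataFrame({
        "primaryid": primaryid[has_outc], "caseid": caseid[has_outc],
        "outc_cod": rng.choice(np.array(vocab.OUTCOME_CODES), int(has_outc.sum()),
                               p=vocab.OUTCOME_WEIGHTS),
    })
    rpsr = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid,
        "rpsr_cod": rng.choice(np.array(vocab.RPSR_CODES), n, p=vocab.RPSR_WEIGHTS),
    })

    tables = {"demo": demo, "drug": drug, "reac": reac, "outc": outc,
              "rpsr": rpsr, "ther": ther, "indi": indi}

    # --- duplicates: clone under a new PRIMARYID, later receipt date ------
    n_dup = int(round(config.duplicate_fraction * n))
    if n_dup:
        dup_rows = rng.choice(n, n_dup, replace=False)
        dup_pid = primaryid[dup_rows] + 1  # same CASEID, higher PRIMARYID
        pid_map = dict(zip(primaryid[dup_rows], dup_pid))
        demo_dup = demo.iloc[dup_rows].copy()
        demo_dup["primaryid"] = dup_pid
        later = fda_day[dup_rows] + rng.integers(1, 400, n_dup)
        demo_dup["fda_dt"] = _dates_to_str(later, np.zeros(n_dup, dtype=bool))
        tables["demo"] = pd.concat([demo, demo_dup], ignore_index=True)
        for name in ("drug", "reac", "outc", "rpsr", "ther", "indi"):
            t = tables[name]
            clone = t[t["primaryid"].isin(pid_map)].copy()
            clone["primaryid"] = clone["primaryid"].map(pid_map)
            tables[name] = pd.concat([t, clone], ignore_index=True)

    tables = {k: schema.coerce_types(v, k)[schema.CANONICAL_COLUMNS[k]]
              for k, v in tables.items()}
    truth = {name: float(m) for name, m in zip(drug_names, mult)}
    return SyntheticCorpus(tables=tables, truth=truth,
                           seed_used=config.seed, config=config)


_FILE_PREFIX = {"demo": "DEMO", "drug": "DRUG", "reac": "REAC", "outc": "OUTC",
                "rpsr": "RPSR", "ther": "THER", "indi": "INDI"}


def _format_cell(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v is pd.NA:
        return ""
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


def write_faers_ascii(corpus: SyntheticCorpus, directory,
                      quarter: str = "24Q4") -> list[str]:
    """Write the seven tables as $-delimited quarterly ASCII files.

    Embedded ``$`` characters are backslash-escaped so free-text drug names
    round-trip; readers must split on unescaped delimiters only.
    Returns the paths written.
    """
    os.makedirs(directory, exist_ok=True)
    paths = []
    for name in schema.TABLES:
        path = os.path.join(directory, f"{_FILE_PREFIX[name]}{quarter}.txt")
        df = corpus.tables[name]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="$", escapechar="\\",
                           quoting=csv.QUOTE_NONE, lineterminator="\n")
            w.writerow([c.upper() for c in df.columns])
            for row in df.itertuples(index=False):
                w.writerow([_format_cell(v) for v in row])
        paths.append(path)
    return paths
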