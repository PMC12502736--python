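"""Shared fixtures: hand-built report stores and a session synthetic corpus."""

import numpy as np
import pandas as pd
import pytest

from pvsweet import schema
from pvsweet.faers import ReportStore, deduplicate
from pvsweet.simulate import SimulationConfig, generate_corpus


def make_store(demo=None, drug=None, reac=None, outc=None, rpsr=None,
               ther=None, indi=None) -> ReportStore:
    """Build a canonical ReportStore from lists of dicts (missing tables empty)."""
    raw = {"demo": demo, "drug": drug, "reac": reac, "outc": outc,
           "rpsr": rpsr, "ther": ther, "indi": indi}
    tables = {}
    for name, rows in raw.items():
        if rows:
            df = pd.DataFrame(rows)
            for col in schema.CANONICAL_COLUMNS[name]:
                if col not in df.columns:
                    df[col] = "" if col not in schema.INT_COLUMNS | schema.FLOAT_COLUMNS else np.nan
            tables[name] = schema.coerce_types(df, name)[schema.CANONICAL_COLUMNS[name]]
        else:
            tables[name] = schema.empty_table(name)
    return ReportStore(tables=tables)


def simple_universe(n=100, drug_reports=10, event_reports=8, overlap=4,
                    drug="drugx", event="Sweet syndrome"):
    """Universe of n reports with controlled drug/event overlap."""
    demo = [{"primaryid": i, "caseid": i, "fda_dt": "20200101"} for i in range(n)]
    drug_rows = [{"primaryid": i, "caseid": i, "drug_seq": 1, "role_cod": "PS",
                  "drugname": drug} for i in range(drug_reports)]
    # other reports get a filler PS drug so exposure is well defined
    drug_rows += [{"primaryid": i, "caseid": i, "drug_seq": 1, "role_cod": "PS",
                   "drugname": "filler"} for i in range(drug_reports, n)]
    event_ids = list(range(overlap)) + list(
        range(drug_reports, drug_reports + event_reports - overlap))
    reac = [{"primaryid": i, "caseid": i, "pt": event} for i in event_ids]
    reac += [{"primaryid": i, "caseid": i, "pt": "Nausea"}
             for i in range(n) if i not in event_ids]
    return make_store(demo=demo, drug=drug_rows, reac=reac)


@pytest.fixture(scope="session")
def planted_store():
    """Deduplicated synthetic store with strong planted signals (seed 11)."""
    cfg = SimulationConfig(
        n_reports=20_000, seed=11, background_event_rate=0.01,
        duplicate_fraction=0.03,
        planted_signals={"azathioprine": 10.0, "azacitidine": 8.0,
                         "filgrastim": 6.0},
    )
    corpus = generate_corpus(cfg)
    store = ReportStore(tables=corpus.tables)
    store, _ = deduplicate(store)
    return store
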