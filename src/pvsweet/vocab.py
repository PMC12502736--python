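"""Bundled vocabularies: default drug catalog, indication pools, term lists.

Everything here is a configurable default, not a licensed dictionary. The
synonym table stands in for WHO-Drug-style name standardization and the ATC
map covers the drugs in the bundled catalog; users supply their own TSVs for
real analyses.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

TARGET_PT = "Sweet syndrome"
TARGET_PT_MEDDRA_CODE = 10042458

#: background reaction PTs for non-target reactions in synthetic corpora
BACKGROUND_PTS = [
    "Nausea", "Pyrexia", "Rash", "Headache", "Fatigue", "Diarrhoea",
    "Vomiting", "Dizziness", "Pruritus", "Dyspnoea", "Arthralgia",
    "Oedema peripheral", "Anaemia", "Neutropenia", "Alopecia",
    "Abdominal pain", "Insomnia", "Cough", "Myalgia", "Urticaria",
    "Hepatotoxicity", "Renal impairment", "Hypotension", "Hypertension",
    "Tachycardia", "Constipation", "Weight decreased", "Malaise",
    "Chills", "Night sweats", "Mucosal inflammation", "Stomatitis",
]

#: indication pools keyed by the catalog's pool tag
INDICATION_POOLS = {
    "malignancy": [
        "Acute myeloid leukaemia", "Myelodysplastic syndrome",
        "Plasma cell myeloma", "Chronic lymphocytic leukaemia",
        "Breast cancer", "Lung neoplasm malignant", "Myelofibrosis",
        "Diffuse large B-cell lymphoma",
    ],
    "immune": [
        "Crohn's disease", "Ulcerative colitis", "Rheumatoid arthritis",
        "Psoriasis", "Systemic lupus erythematosus",
        "Ankylosing spondylitis", "Inflammatory bowel disease",
    ],
    "other": [
        "Hypertension", "Pneumonia", "Urinary tract infection", "Pain",
        "Type 2 diabetes mellitus", "Depression", "Contraception",
        "Gastrooesophageal reflux disease", "Hypothyroidism", "Asthma",
        "Sinusitis", "Prophylaxis",
    ],
}

COUNTRIES = ["US", "FR", "CA", "ES", "JP", "GB", "DE", "IT", "AU", "BR"]
COUNTRY_WEIGHTS = [0.37, 0.12, 0.07, 0.05, 0.05, 0.05, 0.08, 0.07, 0.07, 0.07]

#: OCCP_COD: MD medical doctor, HP other health professional, CN consumer,
#: PH pharmacist, LW lawyer, RN registered nurse, OT other
REPORTER_MIX = {
    "MD": 0.4123, "HP": 0.1947, "CN": 0.0971, "PH": 0.0382,
    "LW": 0.0010, "RN": 0.0005, "OT": 0.2562,
}

OUTCOME_CODES = ["HO", "OT", "LT", "DS", "DE"]
OUTCOME_WEIGHTS = [0.55, 0.30, 0.06, 0.04, 0.05]

RPSR_CODES = ["FGN", "HP", "CSM", "LIT", "OTH"]
RPSR_WEIGHTS = [0.30, 0.35, 0.15, 0.05, 0.15]

#: (drug, ATC level 1, ATC level 2, indication pool tag)
DEFAULT_CATALOG: list[tuple[str, str, str, str]] = [
    ("azathioprine", "L", "L04", "immune"),
    ("adalimumab", "L", "L04", "immune"),
    ("infliximab", "L", "L04", "immune"),
    ("vedolizumab", "L", "L04", "immune"),
    ("methotrexate", "L", "L04", "immune"),
    ("azacitidine", "L", "L01", "malignancy"),
    ("decitabine", "L", "L01", "malignancy"),
    ("venetoclax", "L", "L01", "malignancy"),
    ("bortezomib", "L", "L01", "malignancy"),
    ("ruxolitinib", "L", "L01", "malignancy"),
    ("hydroxycarbamide", "L", "L01", "malignancy"),
    ("cytarabine", "L", "L01", "malignancy"),
    ("lenalidomide", "L", "L04", "malignancy"),
    ("filgrastim", "L", "L03", "malignancy"),
    ("pegfilgrastim", "L", "L03", "malignancy"),
    ("sulfamethoxazole/trimethoprim", "J", "J01", "other"),
    ("levofloxacin", "J", "J01", "other"),
    ("amoxicillin", "J", "J01", "other"),
    ("azithromycin", "J", "J01", "other"),
    ("linezolid", "J", "J01", "other"),
    ("valaciclovir", "J", "J05", "other"),
    ("hydroxychloroquine", "P", "P01", "immune"),
    ("mesalazine", "A", "A07", "immune"),
    ("sulfasalazine", "A", "A07", "immune"),
    ("omeprazole", "A", "A02", "other"),
    ("metformin", "A", "A10", "other"),
    ("paracetamol", "N", "N02", "other"),
    ("diclofenac", "M", "M01", "other"),
    ("gabapentin", "N", "N03", "other"),
    ("sertraline", "N", "N06", "other"),
    ("hydralazine", "C", "C02", "other"),
    ("amlodipine", "C", "C08", "other"),
    ("furosemide", "C", "C03", "other"),
    ("atorvastatin", "C", "C10", "other"),
    ("lisinopril", "C", "C09", "other"),
    ("ethinylestradiol/levonorgestrel", "G", "G03", "other"),
    ("levothyroxine", "H", "H03", "other"),
    ("prednisone", "H", "H02", "immune"),
    ("salbutamol", "R", "R03", "other"),
    ("celecoxib", "M", "M01", "other"),
]


def _read_lines(name: str) -> list[str]:
    text = resources.files("pvsweet.data").joinpath(name).read_text()
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]


def load_term_list(path_or_name) -> list[str]:
    """Load a one-term-per-line list; '#' lines are comments."""
    try:
        with open(path_or_name) as fh:
            lines = fh.read().splitlines()
    except (OSError, TypeError):
        lines = resources.files("pvsweet.data").joinpath(str(path_or_name)).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def default_malignancy_terms() -> list[str]:
    return _read_lines("malignancy_terms.txt")


def default_immune_terms() -> list[str]:
    return _read_lines("immune_terms.txt")


def _read_tsv(name: str, ncol: int) -> list[list[str]]:
    rows = []
    for ln in _read_lines(name):
        parts = [p.strip() for p in ln.split("\t")]
        if len(parts) >= ncol:
            rows.append(parts[:ncol])
    return rows


def default_synonym_map() -> dict[str, str]:
    return {raw.lower(): std for raw, std in _read_tsv("drug_synonyms.tsv", 2)}


def default_atc_map() -> dict[str, tuple[str, str]]:
    return {name: (l1, l2) for name, l1, l2 in _read_tsv("atc_map.tsv", 3)}


def load_synonym_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["raw", "std"])
    return {str(r).strip().lower(): str(s).strip() for r, s in zip(df["raw"], df["std"])}


def load_atc_tsv(path) -> dict[str, tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["name", "atc1", "atc2"])
    return {str(n).strip().lower(): (str(a1).strip(), str(a2).strip())
            for n, a1, a2 in zip(df["name"], df["atc1"], df["atc2"])}
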