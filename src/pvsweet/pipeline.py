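"""End-to-end orchestration: ingest → dedup → cohort → descriptives → TTO →
signals → modeling → network → consistency, with a reproducibility manifest.

Every stage writes plain-text artifacts under the output directory and adds
row counts to the manifest; the configured seeds are recorded so a rerun of
the same configuration is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

from . import descriptives, network, tto
from .cohort import (CaseDefinition, DrugNormalizer, IndicationClassifier,
                     extract_cases)
from .consistency import assemble_matrix, replicate_screen
from .errors import ConfigurationError
from .faers import deduplicate, read_quarters
from .modeling import run_all_schemes
from .signals import screen, volcano_table
from .simulate import SimulationConfig, generate_corpus, write_faers_ascii

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline inputs: either quarterly files or a simulation config."""

    input_paths: list[str] = field(default_factory=list)
    simulation: SimulationConfig | None = None
    definition: CaseDefinition = field(default_factory=CaseDefinition)
    min_cases: int = 3
    schemes: tuple[str, ...] = ("main", "sensitivity_A", "sensitivity_B")
    seed: int = 0
    lasso_folds: int = 10
    lasso_lambdas: int = 100
    network_min_weight: int = 3
    external_corpus: str | None = None
    annotations: str | None = None
    outdir: str = "pv_out"

    def validate(self) -> None:
        if not self.input_paths and self.simulation is None:
            raise ConfigurationError(
                "either input_paths or a simulation config is required")
        for p in list(self.input_paths) + [self.external_corpus,
                                           self.annotations]:
            if p and not os.path.exists(p):
                raise ConfigurationError(f"input path does not exist: {p}")
        if self.simulation is not None:
            self.simulation.validate()


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "status": "running",
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def _stage(name):
        manifest["stages"][name] = {"status": "ok"}
        return manifest["stages"][name]

    out = config.outdir
    try:
        # ingest ----------------------------------------------------------
        st = _stage("ingest")
        if config.simulation is not None:
            corpus = generate_corpus(config.simulation)
            raw_dir = os.path.join(out, "synthetic_quarters")
            write_faers_ascii(corpus, raw_dir)
            store = read_quarters(raw_dir)
            st["synthetic"] = True
            st["truth"] = corpus.truth
        else:
            store = read_quarters(config.input_paths)
            st["input_hashes"] = {p: _hash_file(p) for p in config.input_paths
                                  if os.path.isfile(p)}
        st["raw_reports"] = store.n_reports

        # dedup -----------------------------------------------------------
        st = _stage("dedup")
        store, ledger = deduplicate(store)
        st.update(ledger.summary())

        # cohort ----------------------------------------------------------
        st = _stage("cohort")
        normalizer = DrugNormalizer()
        classifier = IndicationClassifier()
        cases = extract_cases(store, config.definition, normalizer)
        st["n_cases"] = cases.n_cases

        # descriptives ----------------------------------------------------
        st = _stage("descriptives")
        tables = descriptives.summarize_cohort(cases)
        tables["atc"] = descriptives.atc_distribution(cases, normalizer)
        for name, tab in tables.items():
            tab.to_csv(os.path.join(out, f"describe_{name}.tsv"),
                       sep="\t", index=False)
        st["tables"] = sorted(tables)

        # time-to-onset ---------------------------------------------------
        st = _stage("tto")
        records, completeness = tto.compute_latencies(cases)
        st.update(completeness)
        if len(records) >= 1:
            summ = tto.summarize_latency(records)
            st["median_days"] = summ.median
            st["iqr_days"] = [summ.q1, summ.q3]
            summ.bins.to_csv(os.path.join(out, "tto_bins.tsv"),
                             sep="\t", index=False)
        if len(records) >= 10:
            fit = tto.fit_weibull(records)
            st["weibull"] = {"shape": fit.shape, "scale": fit.scale,
                             "converged": fit.converged}
        records.to_csv(os.path.join(out, "tto_records.tsv"), sep="\t",
                       index=False)

        # signals ---------------------------------------------------------
        st = _stage("signals")
        sig = screen(store, definition=config.definition,
                     normalizer=normalizer, min_cases=config.min_cases)
        sig.to_csv(os.path.join(out, "signals.tsv"), sep="\t", index=False)
        volcano_table(sig).to_csv(os.path.join(out, "volcano.tsv"),
                                  sep="\t", index=False)
        st["drugs_tested"] = len(sig)
        st["positive_signals"] = int(sig["signal"].sum())
        md = screen(store, definition=config.definition, normalizer=normalizer,
                    min_cases=config.min_cases, reporter_filter="MD")
        md.to_csv(os.path.join(out, "signals_md_subset.tsv"), sep="\t",
                  index=False)
        st["positive_signals_md_subset"] = int(md["signal"].sum())

        # modeling --------------------------------------------------------
        st = _stage("modeling")
        results, forest, overlap = run_all_schemes(
            store, seed=config.seed, schemes=config.schemes,
            definition=config.definition, normalizer=normalizer,
            classifier=classifier, min_cases=config.min_cases,
            folds=config.lasso_folds, n_lambdas=config.lasso_lambdas)
        forest.to_csv(os.path.join(out, "forest.tsv"), sep="\t", index=False)
        for scheme, r in results.items():
            st[scheme] = {
                "candidates": len(r.candidates),
                "skipped": r.skipped,
                "selected_min": len(r.lasso.selected_min) if r.lasso else 0,
                "auc": r.logistic.auc if r.logistic else None,
                "significant": r.logistic.significant if r.logistic else [],
            }
            if r.lasso:
                r.lasso.cv_table().to_csv(
                    os.path.join(out, f"cv_curve_{scheme}.tsv"),
                    sep="\t", index=False)
        st["overlap"] = sorted(overlap)

        # network ---------------------------------------------------------
        st = _stage("network")
        g = network.build_graph(cases, min_weight=config.network_min_weight,
                                normalizer=normalizer)
        network.edge_table(g).to_csv(os.path.join(out, "network_edges.tsv"),
                                     sep="\t", index=False)
        st["nodes"] = g.number_of_nodes()
        st["edges"] = g.number_of_edges()

        # consistency -----------------------------------------------------
        st = _stage("consistency")
        main = results.get("main")
        main_sig = (main.logistic.significant
                    if main and main.logistic else [])
        main_drugs = [d for d in main_sig if main and d in main.candidates]
        if config.external_corpus and main_drugs:
            ext = replicate_screen(config.external_corpus, drugs=main_drugs,
                                   event_pt=config.definition.event_pt,
                                   normalizer=normalizer,
                                   min_cases=config.min_cases)
            faers_rows = sig[sig["drug"].isin(main_drugs)]
            matrix = assemble_matrix(faers_rows, ext,
                                     annotations=config.annotations,
                                     drugs=main_drugs)
            matrix.to_csv(os.path.join(out, "evidence_matrix.tsv"),
                          sep="\t", index=False)
            st.update(matrix.attrs["overlap_counts"])
        else:
            st["skipped"] = "no external corpus or no main-model drugs"

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        failing = [k for k, v in manifest["stages"].items()]
        manifest["failed_stage"] = failing[-1] if failing else None
        raise
    finally:
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest
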