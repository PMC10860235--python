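"""End-to-end orchestration of the analysis chain on one configuration.

Stages: simulate (or load) the inputs; filter and test expression; call
differentiated and subtype-specific genes; run the NA/HA marker cascades;
search classification marker triples and validate them; merge and normalize
datasets; mine WLAR expression rules; mine literature rules, chain them and
keep terminal-bound chains; assemble, prune and de-overlap the subtype
knowledge graphs; screen subtype-exclusive drugs.  Every stage's outputs and
record counts land in the run directory together with a reproducibility
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import cascade, classify, drugs, expression, graph, io, litmine, simulate, wlar
from .config import PipelineConfig, config_to_dict

log = logging.getLogger("pcoskg")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    run_dir: Path
    truth: simulate.PlantedTruth | None = None
    differentiated: set[str] = field(default_factory=set)
    specific_na: set[str] = field(default_factory=set)
    specific_ha: set[str] = field(default_factory=set)
    na_markers: set[str] = field(default_factory=set)
    ha_markers: set[str] = field(default_factory=set)
    best_triple: classify.MarkerSetTriple | None = None
    best_rate: float = 0.0
    wlar_rules: pd.DataFrame | None = None
    graph_na = None
    graph_ha = None
    graph_mutual = None
    ha_exclusive: set[str] = field(default_factory=set)
    na_exclusive: set[str] = field(default_factory=set)
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, run_dir: str | Path) -> PipelineResult:
    """Execute the full synthetic-study pipeline into ``run_dir``.

    Deterministic for a fixed configuration: rerunning with the same manifest
    configuration reproduces the stochastic stages bit-identically.
    """
    config.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(run_dir=run_dir)
    manifest: dict[str, Any] = {
        "config": config_to_dict(config),
        "seed": config.seed,
        "stages": {},
        "inputs": {},
    }
    result.manifest = manifest
    sim = config.sim

    def record(stage: str, **counts):
        manifest["stages"][stage] = counts
        log.info("stage %s: %s", stage, counts)

    def finish(stage: str | None = None):
        manifest["failed_stage"] = stage
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        stage = "simulate"
        X, labels, truth = simulate.generate_expression(sim)
        Xv, coarse = simulate.generate_validation_expression(sim)
        corpus, corpus_truth = simulate.generate_corpus(sim)
        annotations = simulate.generate_annotations(sim)
        ppi = simulate.generate_ppi(sim)
        drug_table, drug_truth = simulate.generate_drug_table(sim)
        truth.chain_edges = corpus_truth.chain_edges
        result.truth = truth
        io.write_expression(X, run_dir / "expression.tsv")
        io.write_labels(labels, run_dir / "labels.tsv")
        io.write_expression(Xv, run_dir / "validation_expression.tsv")
        io.write_labels(coarse, run_dir / "validation_labels.tsv")
        corpus.to_tsv(run_dir / "corpus.tsv")
        cascade.write_annotations(annotations, run_dir / "annotations.tsv")
        cascade.write_edges(ppi, run_dir / "ppi.tsv")
        io.write_drug_table(drug_table, run_dir / "drug_table.tsv")
        for name in (
            "expression.tsv", "labels.tsv", "corpus.tsv",
            "annotations.tsv", "ppi.tsv", "drug_table.tsv",
        ):
            manifest["inputs"][name] = _sha256(run_dir / name)
        record(stage, n_genes=len(X), n_samples=X.shape[1], n_docs=corpus.n_docs,
               n_terms=len(annotations), n_ppi_edges=len(ppi), n_drug_rows=len(drug_table))

        stage = "expression_filter"
        X = expression.filter_low_expression(X, config.tpm_threshold)
        record(stage, n_genes_kept=len(X))

        stage = "differential"
        d_na_nm = expression.differential_test(X, labels, "NA", "NM")
        d_ha_nm = expression.differential_test(X, labels, "HA", "NM")
        d_na_ha = expression.differential_test(X, labels, "NA", "HA")
        diff_na = expression.call_differentiated(
            d_na_nm, d_na_ha, config.p_cut, config.fc_hi, config.fc_lo
        )
        diff_ha = expression.call_differentiated(
            d_ha_nm, d_na_ha, config.p_cut, config.fc_hi, config.fc_lo
        )
        result.differentiated = diff_na | diff_ha
        result.specific_na = expression.call_specific(
            X, labels, "NA", config.p_cut, config.fc_hi, config.fc_lo
        )
        result.specific_ha = expression.call_specific(
            X, labels, "HA", config.p_cut, config.fc_hi, config.fc_lo
        )
        table = pd.DataFrame(
            {
                "p_na_nm": d_na_nm["p_value"], "fc_na_nm": d_na_nm["fold_change"],
                "p_ha_nm": d_ha_nm["p_value"], "fc_ha_nm": d_ha_nm["fold_change"],
                "p_na_ha": d_na_ha["p_value"], "fc_na_ha": d_na_ha["fold_change"],
            }
        )
        table["specific_call"] = [
            "NA" if g in result.specific_na
            else "HA" if g in result.specific_ha
            else ""
            for g in table.index
        ]
        table.to_csv(run_dir / "differential.tsv", sep="\t", index_label="gene")
        record(stage, n_differentiated=len(result.differentiated),
               n_na_specific=len(result.specific_na),
               n_ha_specific=len(result.specific_ha))

        stage = "marker_cascades"
        term_names = list(annotations["term_name"])
        co_items = sorted(result.specific_na | result.specific_ha) + term_names
        co = litmine.build_cooccurrence(corpus, co_items, config.cooccur_query)
        na_res = cascade.na_cascade(
            result.specific_na, annotations, ppi, co,
            freq_all=config.freq_all, freq_top=config.freq_top,
            top_k=config.top_k_terms, term_p_cut=config.term_p_cut,
        )
        ha_res = cascade.ha_cascade(
            result.specific_ha, annotations, co,
            freq_glucose=config.freq_glucose, term_p_cut=config.term_p_cut,
        )
        result.na_markers = na_res.markers
        result.ha_markers = ha_res.markers
        audit = []
        for label_, res in (("NA", na_res), ("HA", ha_res)):
            for st, genes in res.stages.items():
                audit.append({"cascade": label_, "stage": st,
                              "n_genes": len(genes), "genes": ";".join(sorted(genes))})
        pd.DataFrame(audit).to_csv(run_dir / "cascade_audit.tsv", sep="\t", index=False)
        record(stage, n_na_markers=len(result.na_markers),
               n_ha_markers=len(result.ha_markers),
               na_chosen_term=na_res.chosen_term or "")

        stage = "classifier_search"
        search = classify.search_marker_sets(
            X, labels, n_iter=config.classifier_iterations,
            size_range=(config.size_min, config.size_max), seed=config.seed,
        )
        Xv_f = Xv.loc[Xv.index.intersection(X.index)]
        best = classify.select_best(search, [(Xv_f, coarse)])
        result.best_triple = best
        result.best_rate = max(search.rates) if search.rates else 0.0
        rows = [
            {"group": g, "genes": ";".join(sorted(genes))}
            for g, genes in best.as_dict().items()
        ]
        pd.DataFrame(rows).to_csv(run_dir / "classification_markers.tsv",
                                  sep="\t", index=False)
        record(stage, n_reserved=len(search.reserved),
               best_validation_rate=result.best_rate)

        stage = "merge_normalize"
        merged, merged_labels = expression.merge_and_normalize(
            [X, Xv_f], [labels, coarse], prefixes=["array", "geo"]
        )
        io.write_expression(merged, run_dir / "merged_expression.tsv")
        record(stage, n_genes=len(merged), n_samples=merged.shape[1])

        stage = "wlar"
        wlar_genes = sorted(
            (result.specific_na | result.specific_ha)
            & set(merged.index)
        )
        result.wlar_rules = wlar.compute_wlar(
            merged.loc[wlar_genes],
            conf_cut=config.wlar_conf_cut, supp_cut=config.wlar_supp_cut,
        )
        result.wlar_rules.to_csv(run_dir / "wlar_rules.tsv", sep="\t", index=False)
        record(stage, n_candidate_genes=len(wlar_genes),
               n_rules=len(result.wlar_rules))

        stage = "literature_rules"
        ha_items = sorted(result.specific_ha | result.ha_markers)
        na_items = sorted(result.specific_na | result.na_markers)
        corpus_ha, corpus_na = litmine.partition_corpus(corpus, ha_items, na_items)
        graphs = {}
        for label_, sub, items in (
            ("HA", corpus_ha, ha_items), ("NA", corpus_na, na_items),
        ):
            vocab = sub.vocabulary()
            candidates = sorted(set(items) & set(vocab)) + [
                v for v in vocab if v not in items
            ]
            rules2 = litmine.lit_rules_2(
                sub, candidates, conf_cut=config.lit_conf_cut,
                supp_cut=config.lit_supp_cut, support_mode=config.lit_support_mode,
            )
            rules3 = litmine.extend_rules_3(rules2, conf_cut=config.chain_conf_cut)
            chains = litmine.terminal_filter(rules3, config.terminal)
            rules2.to_csv(run_dir / f"lit_rules2_{label_}.tsv", sep="\t", index=False)
            chains.to_csv(run_dir / f"lit_chains_{label_}.tsv", sep="\t", index=False)
            g = graph.assemble(
                chains, result.wlar_rules, config.terminal,
                gene_items=set(X.index),
            )
            g = graph.prune_low_degree(g, min_degree=config.min_degree)
            graphs[label_] = g
            record(f"{stage}[{label_}]", n_rules2=len(rules2),
                   n_chains=len(chains), n_graph_nodes=g.number_of_nodes(),
                   n_graph_edges=g.number_of_edges())

        stage = "knowledge_graph"
        g_ha, g_na, g_mut = graph.remove_mutual_terms(
            graphs["HA"], graphs["NA"], keep={config.terminal}
        )
        result.graph_ha, result.graph_na, result.graph_mutual = g_ha, g_na, g_mut
        for name, g in (("ha", g_ha), ("na", g_na), ("mutual", g_mut)):
            graph.export(g, run_dir / f"graph_{name}.sif", "sif")
            graph.export(g, run_dir / f"graph_{name}.graphml", "graphml")
            graph.export(g, run_dir / f"graph_{name}.tsv", "tsv")
        record(stage, ha_nodes=g_ha.number_of_nodes(),
               na_nodes=g_na.number_of_nodes(),
               mutual_nodes=g_mut.number_of_nodes())

        stage = "drug_screen"
        ha_all_markers = result.ha_markers | set(best.ha)
        na_all_markers = result.na_markers | set(best.na)
        ha_drugs = drugs.drugs_for(ha_all_markers, drug_table)
        na_drugs = drugs.drugs_for(na_all_markers, drug_table)
        result.ha_exclusive, result.na_exclusive = drugs.exclusive_drugs(
            ha_drugs, na_drugs
        )
        for name, excl, markers in (
            ("ha", result.ha_exclusive, ha_all_markers),
            ("na", result.na_exclusive, na_all_markers),
        ):
            net = drugs.drug_network(
                excl, markers, drug_table,
                min_marker_edges=config.min_drug_marker_edges,
            )
            graph.export(net, run_dir / f"drug_network_{name}.sif", "sif")
            (run_dir / f"exclusive_drugs_{name}.txt").write_text(
                "\n".join(sorted(excl)) + "\n"
            )
        manifest["drug_truth"] = {
            "na_only": sorted(drug_truth.na_only),
            "ha_only": sorted(drug_truth.ha_only),
        }
        record(stage, n_ha_exclusive=len(result.ha_exclusive),
               n_na_exclusive=len(result.na_exclusive))
    except Exception as exc:  # persist partial manifest, then surface the stage
        finish(stage)
        raise StageError(stage, exc) from exc

    finish(None)
    return result
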