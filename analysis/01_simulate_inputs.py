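"""Generate the synthetic study inputs.

Writes the three-group granulosa-cell-style expression matrix (NM / NA / HA,
4 samples each), a coarsely labelled validation matrix, the PubMed-like
term-incidence corpus with planted causal chains, the DAVID-like annotation
table, the STRING-like PPI edge list and the GRNdb-like drug–gene table to
results/data/.
"""

from _common import DATA, study_config

from pcoskg import cascade, io, simulate


def main() -> None:
    sim = study_config().sim
    DATA.mkdir(parents=True, exist_ok=True)

    X, labels, truth = simulate.generate_expression(sim)
    Xv, coarse = simulate.generate_validation_expression(sim)
    corpus, corpus_truth = simulate.generate_corpus(sim)
    annotations = simulate.generate_annotations(sim)
    ppi = simulate.generate_ppi(sim)
    drug_table, drug_truth = simulate.generate_drug_table(sim)

    io.write_expression(X, DATA / "expression.tsv")
    io.write_labels(labels, DATA / "labels.tsv")
    io.write_expression(Xv, DATA / "validation_expression.tsv")
    io.write_labels(coarse, DATA / "validation_labels.tsv")
    corpus.to_tsv(DATA / "corpus.tsv")
    cascade.write_annotations(annotations, DATA / "annotations.tsv")
    cascade.write_edges(ppi, DATA / "ppi.tsv")
    io.write_drug_table(drug_table, DATA / "drug_table.tsv")

    print(f"expression: {X.shape[0]} genes x {X.shape[1]} samples")
    print(f"planted NA-specific: {sorted(truth.specific_na)}")
    print(f"planted HA-specific: {sorted(truth.specific_ha)}")
    print(f"corpus: {corpus.n_docs} documents, "
          f"{len(corpus_truth.chain_edges)} planted chain edges")
    print(f"annotations: {len(annotations)} terms; ppi: {len(ppi)} edges; "
          f"drug table: {len(drug_table)} rows")
    print(f"planted exclusive drugs: NA {sorted(drug_truth.na_only)}, "
          f"HA {sorted(drug_truth.ha_only)}")


if __name__ == "__main__":
    main()
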