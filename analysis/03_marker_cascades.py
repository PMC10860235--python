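"""Filter specific genes to functional markers.

The NA cascade crosses four immunity-term windows (BP/KEGG x all/top-20)
with frequency gates, PPI connectivity, their intersection, a gene–PCOS
co-occurrence gate, and finally the most PCOS-co-occurring immunity term.
The HA cascade uses glucose BP terms (frequency > 1) and the co-occurrence
gate.  Writes marker lists and a stage audit under results/markers/.
"""

import pandas as pd
from _common import DATA, RESULTS, study_config

from pcoskg import cascade, litmine


def main() -> None:
    cfg = study_config()
    diff = pd.read_csv(RESULTS / "differential.tsv", sep="\t", index_col=0,
                       keep_default_na=False)
    na_specific = set(diff.index[diff["specific_call"] == "NA"])
    ha_specific = set(diff.index[diff["specific_call"] == "HA"])
    annotations = cascade.read_annotations(DATA / "annotations.tsv")
    ppi = cascade.read_edges(DATA / "ppi.tsv")
    corpus = litmine.TermIncidence.read_tsv(DATA / "corpus.tsv")

    items = sorted(na_specific | ha_specific) + list(annotations["term_name"])
    co = litmine.build_cooccurrence(corpus, items, cfg.cooccur_query)

    na_res = cascade.na_cascade(
        na_specific, annotations, ppi, co,
        freq_all=cfg.freq_all, freq_top=cfg.freq_top,
        top_k=cfg.top_k_terms, term_p_cut=cfg.term_p_cut,
    )
    ha_res = cascade.ha_cascade(
        ha_specific, annotations, co,
        freq_glucose=cfg.freq_glucose, term_p_cut=cfg.term_p_cut,
    )

    out = RESULTS / "markers"
    out.mkdir(parents=True, exist_ok=True)
    (out / "na_markers.txt").write_text("\n".join(sorted(na_res.markers)) + "\n")
    (out / "ha_markers.txt").write_text("\n".join(sorted(ha_res.markers)) + "\n")
    audit = [
        {"cascade": c, "stage": s, "n": len(g), "genes": ";".join(sorted(g))}
        for c, res in (("NA", na_res), ("HA", ha_res))
        for s, g in res.stages.items()
    ]
    pd.DataFrame(audit).to_csv(out / "cascade_audit.tsv", sep="\t", index=False)

    print(f"NA functional markers ({na_res.chosen_term}): {sorted(na_res.markers)}")
    print(f"HA functional markers: {sorted(ha_res.markers)}")


if __name__ == "__main__":
    main()
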