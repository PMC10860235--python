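"""Mine literature association rules per subtype.

The corpus is partitioned into NA- and HA-centred sub-corpora by marker and
specific-gene mentions; two-element rules (confidence > 0.1, support
> 0.001) are chained into three-element rules (product confidence >= 0.1)
and restricted to chains ending at "female infertility".  Writes
results/lit_rules/.
"""

import pandas as pd
from _common import DATA, RESULTS, study_config

from pcoskg import litmine


def main() -> None:
    cfg = study_config()
    corpus = litmine.TermIncidence.read_tsv(DATA / "corpus.tsv")
    diff = pd.read_csv(RESULTS / "differential.tsv", sep="\t", index_col=0,
                       keep_default_na=False)
    na_items = sorted(diff.index[diff["specific_call"] == "NA"])
    ha_items = sorted(diff.index[diff["specific_call"] == "HA"])

    corpus_ha, corpus_na = litmine.partition_corpus(corpus, ha_items, na_items)
    print(f"corpus: {corpus.n_docs} docs -> "
          f"{corpus_na.n_docs} NA docs, {corpus_ha.n_docs} HA docs")

    out = RESULTS / "lit_rules"
    out.mkdir(parents=True, exist_ok=True)
    for name, sub in (("NA", corpus_na), ("HA", corpus_ha)):
        rules2 = litmine.lit_rules_2(
            sub, sub.vocabulary(), conf_cut=cfg.lit_conf_cut,
            supp_cut=cfg.lit_supp_cut, support_mode=cfg.lit_support_mode,
        )
        rules3 = litmine.extend_rules_3(rules2, conf_cut=cfg.chain_conf_cut)
        chains = litmine.terminal_filter(rules3, cfg.terminal)
        rules2.to_csv(out / f"rules2_{name}.tsv", sep="\t", index=False)
        chains.to_csv(out / f"chains_{name}.tsv", sep="\t", index=False)
        gene_heads = sorted(
            set(chains["a"]) & set(na_items if name == "NA" else ha_items)
        )
        print(f"{name}: {len(rules2)} 2-element rules, {len(rules3)} "
              f"3-element rules, {len(chains)} terminal-bound chains; "
              f"gene chain heads: {gene_heads}")


if __name__ == "__main__":
    main()
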