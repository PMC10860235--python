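"""Mine expression association rules on the merged, normalized data.

The training and validation matrices are merged on shared genes and
quantile-normalized; both discretizations (2- and 4-bin quantile) score
every ordered pair of specific genes, and rules with summed confidence
> 0.6 and summed support > 30 are retained.  Writes results/wlar_rules.tsv.
"""

import pandas as pd
from _common import DATA, RESULTS, study_config

from pcoskg import expression, io, wlar


def main() -> None:
    cfg = study_config()
    X = io.read_expression(DATA / "expression.tsv")
    labels = io.read_labels(DATA / "labels.tsv")
    X = expression.filter_low_expression(X, cfg.tpm_threshold)
    Xv = io.read_expression(DATA / "validation_expression.tsv")
    coarse = io.read_labels(DATA / "validation_labels.tsv")
    Xv = Xv.loc[Xv.index.intersection(X.index)]

    merged, _ = expression.merge_and_normalize(
        [X, Xv], [labels, coarse], prefixes=["array", "geo"]
    )
    print(f"merged matrix: {merged.shape[0]} genes x {merged.shape[1]} samples")

    diff = pd.read_csv(RESULTS / "differential.tsv", sep="\t", index_col=0,
                       keep_default_na=False)
    specific = sorted(
        set(diff.index[diff["specific_call"] != ""]) & set(merged.index)
    )
    rules = wlar.compute_wlar(
        merged.loc[specific], conf_cut=cfg.wlar_conf_cut, supp_cut=cfg.wlar_supp_cut
    )
    rules.to_csv(RESULTS / "wlar_rules.tsv", sep="\t", index=False)
    print(f"{len(rules)} rules retained over {len(specific)} specific genes "
          f"(summed confidence > {cfg.wlar_conf_cut}, "
          f"summed support > {cfg.wlar_supp_cut:g})")
    if not rules.empty:
        top = rules.sort_values("conf_sum", ascending=False).head(3)
        for r in top.itertuples(index=False):
            print(f"  {r.lhs} -> {r.rhs}: conf_sum {r.conf_sum:.2f}, "
                  f"supp_sum {r.supp_sum:g}")


if __name__ == "__main__":
    main()
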