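"""Call differentiated and subtype-specific genes.

Filters genes with mean tpm < 0.1, runs the equal-variance t-test for the
three pairwise group comparisons, calls genes differentiated at p < 0.05
with fold change > 2 or < 0.5, and calls a gene NA- or HA-specific when it
is expressed highest in that subtype and differentiated against both other
groups.  Writes results/differential.tsv.
"""

import pandas as pd
from _common import DATA, RESULTS, study_config

from pcoskg import expression, io


def main() -> None:
    cfg = study_config()
    X = io.read_expression(DATA / "expression.tsv")
    labels = io.read_labels(DATA / "labels.tsv")

    X = expression.filter_low_expression(X, cfg.tpm_threshold)
    print(f"{len(X)} genes pass the mean-tpm filter")

    d_na_nm = expression.differential_test(X, labels, "NA", "NM")
    d_ha_nm = expression.differential_test(X, labels, "HA", "NM")
    d_na_ha = expression.differential_test(X, labels, "NA", "HA")
    diff = expression.call_differentiated(d_na_nm, d_na_ha) | \
        expression.call_differentiated(d_ha_nm, d_na_ha)
    na = expression.call_specific(X, labels, "NA", cfg.p_cut, cfg.fc_hi, cfg.fc_lo)
    ha = expression.call_specific(X, labels, "HA", cfg.p_cut, cfg.fc_hi, cfg.fc_lo)

    table = pd.DataFrame(
        {
            "p_na_nm": d_na_nm["p_value"], "fc_na_nm": d_na_nm["fold_change"],
            "p_ha_nm": d_ha_nm["p_value"], "fc_ha_nm": d_ha_nm["fold_change"],
            "p_na_ha": d_na_ha["p_value"], "fc_na_ha": d_na_ha["fold_change"],
        }
    )
    table["specific_call"] = ["NA" if g in na else "HA" if g in ha else ""
                              for g in table.index]
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "differential.tsv", sep="\t", index_label="gene")

    print(f"{len(diff)} differentiated genes")
    print(f"{len(na)} NA-specific: {sorted(na)}")
    print(f"{len(ha)} HA-specific: {sorted(ha)}")


if __name__ == "__main__":
    main()
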