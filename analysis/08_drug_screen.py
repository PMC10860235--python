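"""Screen subtype-exclusive drugs.

Functional and classification markers per subtype are matched against the
drug–gene interaction table; drugs hitting both subtypes are removed,
leaving exclusive candidates, and the bipartite drug–marker networks are
exported.  Writes results/drugs/.
"""

import pandas as pd
from _common import RESULTS, DATA, study_config

from pcoskg import drugs, graph, io


def main() -> None:
    cfg = study_config()
    table = io.read_drug_table(DATA / "drug_table.tsv")
    markers_dir = RESULTS / "markers"
    na_markers = set((markers_dir / "na_markers.txt").read_text().split())
    ha_markers = set((markers_dir / "ha_markers.txt").read_text().split())
    triples = pd.read_csv(RESULTS / "classification_markers.tsv", sep="\t",
                          keep_default_na=False)
    for row in triples.itertuples(index=False):
        genes = set(row.genes.split(";"))
        if row.group == "NA":
            na_markers |= genes
        elif row.group == "HA":
            ha_markers |= genes

    ha_drugs = drugs.drugs_for(ha_markers, table)
    na_drugs = drugs.drugs_for(na_markers, table)
    ha_only, na_only = drugs.exclusive_drugs(ha_drugs, na_drugs)
    print(f"{len(ha_drugs)} drugs hit HA markers, {len(na_drugs)} hit NA "
          f"markers; exclusive: {len(ha_only)} HA, {len(na_only)} NA")
    print(f"HA-exclusive drugs: {sorted(ha_only)}")
    print(f"NA-exclusive drugs: {sorted(na_only)}")

    out = RESULTS / "drugs"
    out.mkdir(parents=True, exist_ok=True)
    for name, excl, markers in (("ha", ha_only, ha_markers),
                                ("na", na_only, na_markers)):
        (out / f"exclusive_{name}.txt").write_text("\n".join(sorted(excl)) + "\n")
        net = drugs.drug_network(excl, markers, table,
                                 min_marker_edges=cfg.min_drug_marker_edges)
        graph.export(net, out / f"network_{name}.sif", "sif")


if __name__ == "__main__":
    main()
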