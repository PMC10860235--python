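"""Assemble, prune and de-overlap the causal knowledge graphs.

Terminal-bound literature chains are split back into edges, expression
rules between genes already on the graph are merged in, nodes of total
degree < 2 are iteratively peeled (the terminal is kept), and terms shared
by the two subtype graphs are moved to a mutual graph.  Exports SIF,
GraphML and edge TSV under results/graphs/.
"""

import networkx as nx
import pandas as pd
from _common import DATA, RESULTS, study_config

from pcoskg import graph, io


def main() -> None:
    cfg = study_config()
    wlar_rules = pd.read_csv(RESULTS / "wlar_rules.tsv", sep="\t",
                             keep_default_na=False)
    X = io.read_expression(DATA / "expression.tsv")

    graphs = {}
    for name in ("NA", "HA"):
        chains = pd.read_csv(RESULTS / "lit_rules" / f"chains_{name}.tsv",
                             sep="\t", keep_default_na=False)
        g = graph.assemble(chains, wlar_rules, cfg.terminal,
                           gene_items=set(X.index))
        pruned = graph.prune_low_degree(g, min_degree=cfg.min_degree)
        graphs[name] = pruned
        print(f"{name}: {g.number_of_nodes()} nodes assembled, "
              f"{pruned.number_of_nodes()} after pruning")

    g_ha, g_na, g_mut = graph.remove_mutual_terms(
        graphs["HA"], graphs["NA"], keep={cfg.terminal}
    )
    out = RESULTS / "graphs"
    out.mkdir(parents=True, exist_ok=True)
    for name, g in (("na", g_na), ("ha", g_ha), ("mutual", g_mut)):
        for fmt in ("sif", "graphml", "tsv"):
            graph.export(g, out / f"graph_{name}.{fmt}", fmt)

    for name, g in (("NA", g_na), ("HA", g_ha)):
        genes = [n for n, d in g.nodes(data=True) if d.get("type") == "gene"]
        reaching = [n for n in genes if nx.has_path(g, n, cfg.terminal)]
        print(f"{name} graph: {len(genes)} gene nodes, "
              f"{len(reaching)} with a causal path to '{cfg.terminal}'")
    shared = set(graphs["HA"].nodes) & set(graphs["NA"].nodes) - {cfg.terminal}
    print(f"{len(shared)} terms shared by both subtypes moved to the mutual "
          f"graph ({g_mut.number_of_nodes()} nodes with their neighbours)")


if __name__ == "__main__":
    main()
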