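"""Causal knowledge graphs: assembly from literature chains and expression
rules, degree pruning, mutual-term removal and Cytoscape-loadable export.

Graphs are networkx DiGraphs whose nodes carry a ``type`` attribute
(gene / term / terminal) and whose edges carry ``confidence`` and a
``provenance`` set ({literature, transcriptome}).  The designated terminal
phenotype (by default "female infertility") is the sink of every retained
causal chain.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd


def _add_edge(g: nx.DiGraph, u: str, v: str, confidence: float, provenance: str):
    if g.has_edge(u, v):
        data = g.edges[u, v]
        data["confidence"] = max(data["confidence"], confidence)
        data["provenance"] = set(data["provenance"]) | {provenance}
    else:
        g.add_edge(u, v, confidence=float(confidence), provenance={provenance})


def assemble(
    chains3: pd.DataFrame,
    wlar_rules: pd.DataFrame,
    terminal: str,
    gene_items: Iterable[str] = (),
) -> nx.DiGraph:
    """Merge terminal-bound 3-element chains with expression rules.

    Each chain a -> b -> c contributes its two constituent edges with their
    own 2-element confidences.  An expression (WLAR) rule is added only when
    both of its genes already appear in the graph.  Duplicate edges keep the
    maximal confidence and the union of provenances.  Node types are
    inferred: the terminal is typed 'terminal', items in ``gene_items`` are
    'gene', everything else is 'term'.
    """
    g = nx.DiGraph()
    if not chains3.empty:
        for row in chains3.itertuples(index=False):
            _add_edge(g, row.a, row.b, row.conf_ab, "literature")
            _add_edge(g, row.b, row.c, row.conf_bc, "literature")
    if not wlar_rules.empty:
        existing = set(g.nodes)
        for row in wlar_rules.itertuples(index=False):
            if row.lhs in existing and row.rhs in existing:
                _add_edge(g, row.lhs, row.rhs, row.conf_sum, "transcriptome")
    genes = {x for x in gene_items}
    for node in g.nodes:
        if node.casefold() == terminal.casefold():
            g.nodes[node]["type"] = "terminal"
        elif node in genes:
            g.nodes[node]["type"] = "gene"
        else:
            g.nodes[node]["type"] = "term"
    return g


def prune_low_degree(g: nx.DiGraph, min_degree: int = 2) -> nx.DiGraph:
    """Iteratively peel non-terminal nodes of total degree below min_degree.

    Peeling repeats to a fixed point, since removing a node can strand new
    low-degree neighbours; terminal-typed nodes are always kept.
    """
    out = g.copy()
    while True:
        doomed = [
            n
            for n in out.nodes
            if out.nodes[n].get("type") != "terminal"
            and out.degree(n) < min_degree
        ]
        if not doomed:
            return out
        out.remove_nodes_from(doomed)


def remove_mutual_terms(
    g_ha: nx.DiGraph,
    g_na: nx.DiGraph,
    keep: Iterable[str] = (),
) -> tuple[nx.DiGraph, nx.DiGraph, nx.DiGraph]:
    """Remove nodes shared by both subtype graphs into a third 'mutual' graph.

    Nodes listed in ``keep`` (the terminal, typically) stay in both graphs.
    The mutual graph holds the removed nodes together with their incident
    edges from either input graph.
    """
    keep_cf = {k.casefold() for k in keep}
    shared = {
        n for n in set(g_ha.nodes) & set(g_na.nodes) if n.casefold() not in keep_cf
    }
    mutual = nx.DiGraph()
    for n in shared:
        attrs = dict(g_ha.nodes[n]) or dict(g_na.nodes[n])
        mutual.add_node(n, **attrs)
    for src in (g_ha, g_na):
        for u, v, data in src.edges(data=True):
            if u in shared or v in shared:
                if mutual.has_edge(u, v):
                    mutual.edges[u, v]["confidence"] = max(
                        mutual.edges[u, v]["confidence"], data["confidence"]
                    )
                    mutual.edges[u, v]["provenance"] = set(
                        mutual.edges[u, v]["provenance"]
                    ) | set(data["provenance"])
                else:
                    for n in (u, v):
                        if n not in mutual:
                            g = src if n in src else None
                            mutual.add_node(n, **(dict(src.nodes[n]) if g else {}))
                    mutual.add_edge(
                        u, v,
                        confidence=data["confidence"],
                        provenance=set(data["provenance"]),
                    )
    ha_out = g_ha.copy()
    na_out = g_na.copy()
    ha_out.remove_nodes_from(shared)
    na_out.remove_nodes_from(shared)
    return ha_out, na_out, mutual


def write_sif(g: nx.DiGraph, path: str | Path) -> None:
    """Simple Interaction Format: one "source causes target" line per edge."""
    with open(path, "w") as fh:
        for u, v in sorted(g.edges):
            fh.write(f"{u}\tcauses\t{v}\n")


def write_edge_tsv(g: nx.DiGraph, path: str | Path) -> None:
    rows = [
        {
            "source": u,
            "target": v,
            "confidence": d["confidence"],
            "provenance": ",".join(sorted(d["provenance"])),
        }
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "confidence", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(g: nx.DiGraph, path: str | Path) -> None:
    out = g.copy()
    for _, _, data in out.edges(data=True):
        data["provenance"] = ",".join(sorted(data["provenance"]))
    nx.write_graphml(out, str(path))


def read_graphml(path: str | Path) -> nx.DiGraph:
    g = nx.read_graphml(str(path))
    out = nx.DiGraph()
    for n, data in g.nodes(data=True):
        out.add_node(n, **data)
    for u, v, data in g.edges(data=True):
        data = dict(data)
        data["provenance"] = set(p for p in data.get("provenance", "").split(",") if p)
        data["confidence"] = float(data.get("confidence", 0.0))
        out.add_edge(u, v, **data)
    return out


def export(g: nx.DiGraph, path: str | Path, fmt: str) -> None:
    """Write the graph as 'sif', 'graphml' or 'tsv'."""
    writers = {"sif": write_sif, "graphml": write_graphml, "tsv": write_edge_tsv}
    if fmt not in writers:
        raise ValueError(f"unknown export format {fmt!r}; choose from {sorted(writers)}")
    writers[fmt](g, path)
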