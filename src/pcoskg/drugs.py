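"""Subtype-exclusive drug screening from a drug–gene interaction table.

A drug is a candidate for a subtype when it interacts with at least one of
that subtype's marker genes; drugs hitting both subtypes' markers are
removed from both lists, leaving the exclusive sets.  A bipartite
drug -> gene network restricted to the exclusive drugs (weighted by the
interaction score, maximum over duplicate evidence rows) is exported in the
same formats as the knowledge graph.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import pandas as pd

TABLE_COLUMNS = ["drug", "gene", "score"]


def validate_drug_table(table: pd.DataFrame) -> None:
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"drug table missing columns: {sorted(missing)}")


def drugs_for(markers: Iterable[str], table: pd.DataFrame) -> set[str]:
    """Drugs with at least one interaction row whose gene is a marker.

    Drug names are canonicalized case-insensitively (first spelling wins).
    """
    validate_drug_table(table)
    marker_set = set(markers)
    canonical: dict[str, str] = {}
    hits: set[str] = set()
    for drug, gene in zip(table["drug"], table["gene"]):
        name = canonical.setdefault(str(drug).casefold(), str(drug))
        if gene in marker_set:
            hits.add(name)
    return hits


def exclusive_drugs(
    ha_drugs: Iterable[str], na_drugs: Iterable[str]
) -> tuple[set[str], set[str]]:
    """Drugs exclusive to each subtype: shared drugs drop from both lists."""
    ha = set(ha_drugs)
    na = set(na_drugs)
    ha_cf = {d.casefold() for d in ha}
    na_cf = {d.casefold() for d in na}
    return (
        {d for d in ha if d.casefold() not in na_cf},
        {d for d in na if d.casefold() not in ha_cf},
    )


def drug_network(
    exclusive: Iterable[str],
    markers: Iterable[str],
    table: pd.DataFrame,
    min_marker_edges: int = 1,
) -> nx.DiGraph:
    """Bipartite drug -> marker network for the exclusive drugs.

    Edge weight is the interaction score (maximum over duplicate rows);
    drugs with fewer than ``min_marker_edges`` marker interactions are
    dropped.
    """
    validate_drug_table(table)
    drug_cf = {d.casefold(): d for d in exclusive}
    marker_set = set(markers)
    best: dict[tuple[str, str], float] = {}
    for drug, gene, score in zip(table["drug"], table["gene"], table["score"]):
        name = drug_cf.get(str(drug).casefold())
        if name is None or gene not in marker_set:
            continue
        key = (name, gene)
        best[key] = max(best.get(key, float("-inf")), float(score))
    counts: dict[str, int] = {}
    for drug, _ in best:
        counts[drug] = counts.get(drug, 0) + 1
    g = nx.DiGraph()
    for (drug, gene), score in best.items():
        if counts[drug] < min_marker_edges:
            continue
        g.add_node(drug, type="drug")
        g.add_node(gene, type="gene")
        g.add_edge(drug, gene, confidence=score, provenance={"drug_gene"})
    return g
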