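"""Functional-marker filtering cascades over annotation terms, PPI
connectivity and literature co-occurrence.

The NA cascade filters NA-specific genes through four immunity-term windows
(BP all significant terms, BP top-20, KEGG all, KEGG top-20) with appearance
frequencies > 5 (all-terms windows) and > 2 (top-20 windows), per-window PPI
connectivity, intersection of the four survivor sets, a gene–PCOS
co-occurrence gate (> 0), and finally picks the term with the largest
co-occurrence count among terms carrying at least two survivors.  The HA
cascade is shorter: glucose-flagged BP terms with frequency > 1, then the
co-occurrence gate.  Curation of term categories ("manually picked" in the
original workflow) arrives as a data column, not code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

ANNOTATION_COLUMNS = ["term_id", "term_name", "category", "source", "p_value", "genes"]
IMMUNITY_CATEGORIES = frozenset({"immunity", "immunity_related"})


def validate_annotations(terms: pd.DataFrame) -> None:
    missing = set(ANNOTATION_COLUMNS) - set(terms.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if terms["term_id"].duplicated().any():
        raise ValueError("duplicate term_ids")
    p = terms["p_value"]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p_value outside [0, 1]")


def term_frequency(genes: Iterable[str], terms: pd.DataFrame) -> dict[str, int]:
    """For each gene, the number of distinct terms whose member set holds it."""
    counts = {g: 0 for g in genes}
    for members in terms["genes"]:
        for g in counts:
            if g in members:
                counts[g] += 1
    return counts


def select_top_terms(
    terms: pd.DataFrame, k: int = 20, p_cut: float = 0.05
) -> pd.DataFrame:
    """Significant terms (p < p_cut) sorted ascending by p, first k.

    Ties at the k-th p-value break by lexicographic term_id so output is
    deterministic; fewer than k survivors returns them all with a warning.
    """
    if terms.empty:
        raise ValueError("empty annotation table")
    survivors = terms[terms["p_value"] < p_cut]
    survivors = survivors.sort_values(["p_value", "term_id"], kind="mergesort")
    if len(survivors) < k:
        warnings.warn(
            f"only {len(survivors)} terms with p < {p_cut}; requested top {k}"
        )
    return survivors.head(k).reset_index(drop=True)


def connectivity_filter(
    genes: Iterable[str], edges: pd.DataFrame
) -> set[str]:
    """Genes sharing at least one PPI edge with another gene of the input set."""
    gene_set = set(genes)
    connected: set[str] = set()
    for a, b in zip(edges["gene_a"], edges["gene_b"]):
        if a != b and a in gene_set and b in gene_set:
            connected.add(a)
            connected.add(b)
    return connected


def cooccurrence_filter(
    genes: Iterable[str], co: Mapping[str, int], min_count: int = 1
) -> set[str]:
    """Genes whose co-occurrence count reaches min_count; absent key = 0."""
    return {g for g in genes if co.get(g, 0) >= min_count}


@dataclass
class CascadeResult:
    """Final markers plus a per-stage audit of surviving gene sets."""

    markers: set[str]
    chosen_term: str | None = None
    stages: dict[str, set[str]] = field(default_factory=dict)


def _stage_warn(stage: str) -> None:
    warnings.warn(f"cascade produced an empty gene set at stage: {stage}")


def na_cascade(
    na_specific: Iterable[str],
    annotations: pd.DataFrame,
    edges: pd.DataFrame,
    cooccur: Mapping[str, int],
    freq_all: int = 5,
    freq_top: int = 2,
    top_k: int = 20,
    term_p_cut: float = 0.05,
) -> CascadeResult:
    """The NA-PCOS functional-marker cascade.

    Stages: (1) immunity(+related) terms under the four windows; (2)
    appearance frequency > freq_all (all-terms windows) and > freq_top
    (top-20 windows); (3) per-window PPI connectivity; (4) intersection of
    the four windows; (5) gene–PCOS co-occurrence > 0; (6) among terms with
    >= 2 surviving genes, the one with the largest term–PCOS co-occurrence
    (ties: lowest p, then term_id) donates the final markers.
    """
    validate_annotations(annotations)
    specific = set(na_specific)
    result = CascadeResult(markers=set())

    sig = annotations[annotations["p_value"] < term_p_cut]
    windows: dict[str, pd.DataFrame] = {}
    for source in ("BP", "KEGG"):
        by_source = sig[sig["source"] == source]
        top = select_top_terms(annotations[annotations["source"] == source],
                               k=top_k, p_cut=term_p_cut)
        windows[f"{source}_all"] = by_source[
            by_source["category"].isin(IMMUNITY_CATEGORIES)
        ]
        windows[f"{source}_top{top_k}"] = top[
            top["category"].isin(IMMUNITY_CATEGORIES)
        ]

    window_survivors: dict[str, set[str]] = {}
    immunity_terms = []
    for name, window in windows.items():
        immunity_terms.append(window)
        cut = freq_all if name.endswith("_all") else freq_top
        freq = term_frequency(specific, window)
        on_terms = {g for g, c in freq.items() if c > 0}
        result.stages[f"on_terms[{name}]"] = on_terms
        frequent = {g for g, c in freq.items() if c > cut}
        result.stages[f"frequency[{name}]"] = frequent
        connected = connectivity_filter(frequent, edges)
        result.stages[f"connectivity[{name}]"] = connected
        window_survivors[name] = connected

    intersection = set.intersection(*window_survivors.values())
    result.stages["intersection"] = intersection
    if not intersection:
        _stage_warn("intersection")
        return result

    reserved = cooccurrence_filter(intersection, cooccur, min_count=1)
    result.stages["cooccurrence"] = reserved
    if not reserved:
        _stage_warn("cooccurrence")
        return result

    candidates = pd.concat(immunity_terms).drop_duplicates("term_id")
    rows = []
    for row in candidates.itertuples(index=False):
        on_term = reserved & set(row.genes)
        if len(on_term) >= 2:
            rows.append((row.term_id, row.term_name, row.p_value, on_term))
    if not rows:
        _stage_warn("term selection")
        result.markers = set()
        return result
    rows.sort(key=lambda r: (-cooccur.get(r[1], 0), r[2], r[0]))
    term_id, _, _, markers = rows[0]
    result.markers = markers
    result.chosen_term = term_id
    return result


def ha_cascade(
    ha_specific: Iterable[str],
    annotations: pd.DataFrame,
    cooccur: Mapping[str, int],
    freq_glucose: int = 1,
    term_p_cut: float = 0.05,
) -> CascadeResult:
    """The HA-PCOS cascade: glucose BP terms, frequency > 1, co-occurrence > 0.

    Frequency is counted over glucose-flagged BP terms only; the KEGG source
    is not consulted for this subtype.
    """
    validate_annotations(annotations)
    specific = set(ha_specific)
    result = CascadeResult(markers=set())

    glucose = annotations[
        (annotations["source"] == "BP")
        & (annotations["category"] == "glucose")
        & (annotations["p_value"] < term_p_cut)
    ]
    freq = term_frequency(specific, glucose)
    frequent = {g for g, c in freq.items() if c > freq_glucose}
    result.stages["frequency"] = frequent
    if not frequent:
        _stage_warn("frequency")
        return result
    reserved = cooccurrence_filter(frequent, cooccur, min_count=1)
    result.stages["cooccurrence"] = reserved
    if not reserved:
        _stage_warn("cooccurrence")
    result.markers = reserved
    return result


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["p_value"] = df["p_value"].astype(float)
    df["genes"] = df["genes"].map(
        lambda s: frozenset(g for g in str(s).split(";") if g)
    )
    validate_annotations(df)
    return df


def write_annotations(terms: pd.DataFrame, path) -> None:
    out = terms.copy()
    out["genes"] = out["genes"].map(lambda s: ";".join(sorted(s)))
    out.to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)
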