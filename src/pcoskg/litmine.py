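"""Literature mining: term-incidence corpora, co-occurrence counts and
association-rule chaining.

A corpus is a map from document id (PMID-like string) to the set of items —
MeSH terms qualified by an allow-listed subheading, plus gene symbols found
in the abstract text.  Rules are conditional document frequencies:
confidence(A -> B) = |docs(A) ∩ docs(B)| / |docs(A)|, and support is the
(optionally corpus-normalized) additive prevalence |docs(A)| + |docs(B)|.
Two-element rules are chained into three-element rules whose confidence is
the product of the constituents, and chains are finally restricted to those
terminating at a designated phenotype (by default "female infertility").
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: MeSH subheadings whose qualified terms are treated as mechanistic items.
DEFAULT_SUBHEADINGS = frozenset(
    {"metabolism", "chemical", "genetics", "drug effects", "immunology"}
)


class TermIncidence:
    """Document -> item-set incidence with case-insensitive item lookup."""

    def __init__(self, doc_items: Mapping[str, Iterable[str]]):
        self._docs: dict[str, frozenset[str]] = {
            str(doc): frozenset(str(i) for i in items)
            for doc, items in doc_items.items()
        }
        if any(not item for items in self._docs.values() for item in items):
            raise ValueError("items must be non-empty strings")
        # postings keyed by casefolded item; canonical spelling kept for output
        self._postings: dict[str, set[str]] = {}
        self._canonical: dict[str, str] = {}
        for doc, items in self._docs.items():
            for item in items:
                key = item.casefold()
                self._postings.setdefault(key, set()).add(doc)
                self._canonical.setdefault(key, item)

    @property
    def n_docs(self) -> int:
        return len(self._docs)

    @property
    def doc_ids(self) -> list[str]:
        return sorted(self._docs)

    def items_of(self, doc_id: str) -> frozenset[str]:
        return self._docs[doc_id]

    def vocabulary(self) -> list[str]:
        return sorted(self._canonical.values())

    def docs_with(self, item: str) -> frozenset[str]:
        return frozenset(self._postings.get(item.casefold(), ()))

    def subset(self, doc_ids: Iterable[str]) -> "TermIncidence":
        keep = set(doc_ids)
        return TermIncidence({d: i for d, i in self._docs.items() if d in keep})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("doc_id\titems\n")
            for doc in sorted(self._docs):
                fh.write(f"{doc}\t{';'.join(sorted(self._docs[doc]))}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TermIncidence":
        docs: dict[str, list[str]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("doc_id"):
                raise ValueError(f"{path}: expected a doc_id/items header")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                doc, _, items = line.partition("\t")
                docs[doc] = [i for i in items.split(";") if i]
        return cls(docs)

    def __eq__(self, other) -> bool:
        return isinstance(other, TermIncidence) and self._docs == other._docs

    def __repr__(self) -> str:
        return f"TermIncidence(n_docs={self.n_docs}, n_items={len(self._postings)})"


def extract_items(
    records: Iterable[Mapping],
    subheadings: frozenset[str] = DEFAULT_SUBHEADINGS,
    gene_symbols: Sequence[str] = (),
) -> TermIncidence:
    """Turn raw abstract records into a :class:`TermIncidence`.

    Each record is a mapping with keys ``id``, ``mesh`` (list of
    "Term/subheading" strings) and ``text``.  A MeSH term is kept when its
    subheading is allow-listed; a gene symbol is added when it occurs in the
    text as a whole word (case-sensitive, as symbols are conventionally
    upper-case).  Records without an id are skipped with a warning.
    """
    allowed = {s.casefold() for s in subheadings}
    patterns = [
        (sym, re.compile(rf"\b{re.escape(sym)}\b")) for sym in gene_symbols
    ]
    docs: dict[str, set[str]] = {}
    for rec in records:
        doc_id = rec.get("id")
        if not doc_id:
            warnings.warn("skipping record without a document id")
            continue
        items: set[str] = set()
        for mesh in rec.get("mesh", ()):
            term, _, sub = str(mesh).partition("/")
            if sub.casefold() in allowed and term:
                items.add(term)
        text = rec.get("text", "")
        for sym, pat in patterns:
            if pat.search(text):
                items.add(sym)
        docs[str(doc_id)] = items
    return TermIncidence({d: i for d, i in docs.items() if i})


def read_records_jsonl(path: str | Path) -> list[dict]:
    """Raw abstract records from JSON-lines: {"id", "mesh": [...], "text"}."""
    import json

    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return records


def partition_corpus(
    inc: TermIncidence,
    ha_items: Iterable[str],
    na_items: Iterable[str],
) -> tuple[TermIncidence, TermIncidence]:
    """Split a corpus into HA-PCOS and NA-PCOS sub-corpora.

    A document belongs to a sub-corpus when it mentions at least one of that
    subtype's marker/differentiated genes; documents may belong to both, and
    documents mentioning neither are dropped.
    """
    ha_docs: set[str] = set()
    for item in ha_items:
        ha_docs |= inc.docs_with(item)
    na_docs: set[str] = set()
    for item in na_items:
        na_docs |= inc.docs_with(item)
    return inc.subset(ha_docs), inc.subset(na_docs)


def cooccurrence_count(inc: TermIncidence, a: str, b: str) -> int:
    """Number of documents containing both items (case-insensitive)."""
    return len(inc.docs_with(a) & inc.docs_with(b))


def build_cooccurrence(
    inc: TermIncidence, items: Iterable[str], query: str
) -> dict[str, int]:
    """Co-occurrence counts of each item with a fixed query string.

    Emulates searching '"item" and "query"' and recording the number of hits.
    """
    return {item: cooccurrence_count(inc, item, query) for item in items}


RULE2_COLUMNS = ["lhs", "rhs", "confidence", "support", "n_lhs", "n_rhs", "n_both"]


def lit_rules_2(
    inc: TermIncidence,
    items: Sequence[str],
    conf_cut: float = 0.1,
    supp_cut: float = 0.001,
    support_mode: str = "fraction",
) -> pd.DataFrame:
    """Directed two-element literature rules over the candidate items.

    Both directions of every unordered pair are evaluated.  Confidence is the
    conditional document frequency; support is |docs(A)| + |docs(B)| divided
    by the corpus size under the default ``fraction`` mode (``count`` keeps
    the raw additive count).  Rules strictly above both cuts are retained.
    """
    if inc.n_docs == 0:
        raise ValueError("corpus is empty")
    if support_mode not in ("fraction", "count"):
        raise ValueError("support_mode must be 'fraction' or 'count'")
    denom = inc.n_docs if support_mode == "fraction" else 1
    postings = {item: inc.docs_with(item) for item in items}
    rows = []
    for a in items:
        docs_a = postings[a]
        if not docs_a:
            continue
        for b in items:
            if a.casefold() == b.casefold():
                continue
            docs_b = postings[b]
            n_both = len(docs_a & docs_b)
            conf = n_both / len(docs_a)
            supp = (len(docs_a) + len(docs_b)) / denom
            if conf > conf_cut and supp > supp_cut:
                rows.append((a, b, conf, supp, len(docs_a), len(docs_b), n_both))
    return pd.DataFrame(rows, columns=RULE2_COLUMNS)


RULE3_COLUMNS = ["a", "b", "c", "confidence", "conf_ab", "conf_bc"]


def extend_rules_3(rules2: pd.DataFrame, conf_cut: float = 0.1) -> pd.DataFrame:
    """Chain two-element rules A->B and B->C into A->B->C.

    Chain confidence is the product of the constituent confidences; elements
    must be pairwise distinct; chains with confidence below the cut are
    removed.
    """
    if rules2.empty:
        return pd.DataFrame(columns=RULE3_COLUMNS)
    rows = []
    by_lhs: dict[str, list[tuple[str, float]]] = {}
    for r in rules2.itertuples(index=False):
        by_lhs.setdefault(r.lhs, []).append((r.rhs, r.confidence))
    for r in rules2.itertuples(index=False):
        for c, conf_bc in by_lhs.get(r.rhs, ()):
            if c == r.lhs or c == r.rhs:
                continue
            conf = r.confidence * conf_bc
            if conf >= conf_cut:
                rows.append((r.lhs, r.rhs, c, conf, r.confidence, conf_bc))
    return pd.DataFrame(rows, columns=RULE3_COLUMNS)


def terminal_filter(
    rules3: pd.DataFrame, terminal: str = "female infertility"
) -> pd.DataFrame:
    """Keep only three-element chains whose third element is the terminal."""
    if rules3.empty:
        return rules3.copy()
    mask = rules3["c"].str.casefold() == terminal.casefold()
    return rules3[mask].reset_index(drop=True)
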