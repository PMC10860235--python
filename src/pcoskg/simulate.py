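"""Synthetic study generator with planted ground truth.

Emulates every input of the analysis chain: a tpm-scale gene × sample
expression matrix over three groups (NM, NA, HA) with planted
subtype-specific genes; a PubMed-like term-incidence corpus with planted
conditional co-occurrence chains ending at "female infertility"; a
DAVID-like annotation table with immunity/glucose category flags; a
STRING-like PPI edge list; and a GRNdb-like drug–gene interaction table with
planted subtype-exclusive drugs.

Expression model: per-gene log-normal baseline with an i.i.d. log-scale
noise term per cell; planted genes carry a multiplicative fold effect in
their target group, so their target-group mean is ``fold`` times baseline in
expectation.  Corpus model: per-document independent item draws, with chain
intermediates generated conditionally on their head so the planted
conditional probabilities are exactly identifiable.  All randomness derives
from the single config seed via fixed per-generator seed-sequence streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .litmine import TermIncidence

GROUPS = ("NM", "NA", "HA")

# fixed stream ids so each generator is independently reproducible
_STREAM_EXPRESSION = 1
_STREAM_CORPUS = 2
_STREAM_ANNOTATIONS = 3
_STREAM_PPI = 4
_STREAM_DRUGS = 5


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators."""

    specific_na: frozenset[str] = frozenset()
    specific_ha: frozenset[str] = frozenset()
    chain_edges: tuple[tuple[str, str], ...] = ()
    marker_annotations: dict[str, frozenset[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class DrugTruth:
    """Planted exclusivity structure of the synthetic drug table."""

    na_only: frozenset[str]
    ha_only: frozenset[str]
    shared: frozenset[str]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def gene_ids(config: SimConfig) -> tuple[list[str], list[str], list[str], list[str]]:
    """Deterministic gene naming: planted NA, HA, NM, then background."""
    na = [f"NAG{i + 1:02d}" for i in range(config.n_specific_na)]
    ha = [f"HAG{i + 1:02d}" for i in range(config.n_specific_ha)]
    nm = [f"NMG{i + 1:02d}" for i in range(config.n_specific_nm)]
    n_bg = config.n_genes - len(na) - len(ha) - len(nm)
    bg = [f"G{i + 1:04d}" for i in range(n_bg)]
    return na, ha, nm, bg


def sample_ids(config: SimConfig) -> tuple[list[str], pd.Series]:
    samples, groups = [], []
    for g in GROUPS:
        for i in range(config.n_per_group):
            samples.append(f"{g}_{i + 1}")
            groups.append(g)
    return samples, pd.Series(groups, index=samples, name="group")


def generate_expression(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, PlantedTruth]:
    """Simulate the gene × sample tpm matrix with planted specific genes.

    Returns the matrix (genes × samples), the sample -> group labels, and the
    planted truth.  Planted genes draw their baseline from the upper part of
    the baseline distribution so they survive the low-expression filter.
    """
    config.validate()
    na, ha, nm, bg = gene_ids(config)
    genes = na + ha + nm + bg
    samples, labels = sample_ids(config)

    rng = _rng(config, _STREAM_EXPRESSION)
    mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    # planted genes: baseline safely above the tpm filter
    n_planted = len(na) + len(ha) + len(nm)
    mu[:n_planted] = rng.normal(2.0, 0.5, n_planted)
    noise = rng.normal(0.0, config.noise_sd, (config.n_genes, len(samples)))
    values = np.exp(mu[:, None] + noise)

    X = pd.DataFrame(values, index=genes, columns=samples)
    X.loc[na, labels[labels == "NA"].index] *= config.fold
    X.loc[ha, labels[labels == "HA"].index] *= config.fold
    X.loc[nm, labels[labels == "NM"].index] *= config.fold

    truth = PlantedTruth(specific_na=frozenset(na), specific_ha=frozenset(ha))
    return X, labels, truth


def generate_validation_expression(
    config: SimConfig, n_nm: int = 6, n_pcos: int = 12
) -> tuple[pd.DataFrame, pd.Series]:
    """A coarsely labelled (NM / PCOS) validation matrix from the same model.

    PCOS samples split evenly between latent NA-like and HA-like states, but
    only the coarse label is returned — emulating public PCOS datasets whose
    subtype is unknown.
    """
    config.validate()
    na, ha, nm, bg = gene_ids(config)
    genes = na + ha + nm + bg
    rng = _rng(config, _STREAM_EXPRESSION + 10)
    mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    n_planted = len(na) + len(ha) + len(nm)
    mu[:n_planted] = rng.normal(2.0, 0.5, n_planted)

    n_na = n_pcos // 2
    n_ha = n_pcos - n_na
    cols = (
        [f"VNM_{i + 1}" for i in range(n_nm)]
        + [f"VPC_{i + 1}" for i in range(n_pcos)]
    )
    latent = ["NM"] * n_nm + ["NA"] * n_na + ["HA"] * n_ha
    noise = rng.normal(0.0, config.noise_sd, (config.n_genes, len(cols)))
    values = np.exp(mu[:, None] + noise)
    X = pd.DataFrame(values, index=genes, columns=cols)
    for j, state in enumerate(latent):
        if state == "NA":
            X.iloc[: len(na), j] *= config.fold
        elif state == "HA":
            X.iloc[len(na) : len(na) + len(ha), j] *= config.fold
        else:
            X.iloc[len(na) + len(ha) : len(na) + len(ha) + len(nm), j] *= config.fold
    coarse = pd.Series(
        ["NM"] * n_nm + ["PCOS"] * n_pcos, index=cols, name="group"
    )
    return X, coarse


def generate_corpus(config: SimConfig) -> tuple[TermIncidence, PlantedTruth]:
    """Simulate the term-incidence corpus with planted conditional chains.

    Each document carries a latent topic (NA, HA or general); planted gene
    mentions are confined to their subtype's topic, so literature about the
    two subtypes barely overlaps, while background MeSH terms are
    topic-independent.  For each planted chain (a, b, terminal, p_ab, p_bt):
    the head ``a`` occurs with its base marginal probability (inside its
    topic); ``b`` occurs in a document containing ``a`` with probability
    exactly ``p_ab`` (and nowhere else, unless another chain also produces
    it); the terminal occurs given ``b`` with probability ``p_bt``.  Planted
    genes that head no chain still occur at a small base rate so their
    co-occurrence with background terms (e.g. "PCOS") is observable.
    """
    config.validate()
    if not config.planted_chains:
        raise ValueError("planted_chains must be nonempty")
    rng = _rng(config, _STREAM_CORPUS)
    n = config.n_docs

    downstream = {c.b for c in config.planted_chains} | {
        c.terminal for c in config.planted_chains
    }

    # latent topics: 0 = general, 1 = NA, 2 = HA
    topic = rng.choice(
        3,
        size=n,
        p=[
            1.0 - config.na_topic_share - config.ha_topic_share,
            config.na_topic_share,
            config.ha_topic_share,
        ],
    )
    na, ha, _, _ = gene_ids(config)
    topic_of = {g: 1 for g in na}
    topic_of.update({g: 2 for g in ha})
    shares = {1: config.na_topic_share, 2: config.ha_topic_share}

    def item_presence(item: str, marginal_p: float) -> np.ndarray:
        """Presence mask with the stated marginal, confined to the topic."""
        t = topic_of.get(item)
        if t is None:
            return rng.random(n) < marginal_p
        return (topic == t) & (rng.random(n) < min(1.0, marginal_p / shares[t]))

    presence: dict[str, np.ndarray] = {}
    # background vocabulary, excluding chain downstream items whose presence
    # is owned by the conditional chain logic
    for item, p in config.background_items.items():
        if item in downstream:
            continue
        presence[item] = rng.random(n) < p
    for i in range(config.n_filler_terms):
        presence[f"MeSH_{i + 1:03d}"] = rng.random(n) < config.filler_term_p
    # planted genes not heading a chain: small base rate inside their topic
    heads = {c.a for c in config.planted_chains}
    for gene in na + ha:
        if gene not in downstream and gene not in heads and gene not in presence:
            presence[gene] = item_presence(gene, config.gene_doc_p)
    # chain heads that nothing else produces
    for c in config.planted_chains:
        if c.a not in presence and c.a not in downstream:
            presence[c.a] = item_presence(c.a, config.chain_head_p)
    # chain intermediates in dependency order: a chain may only fire once
    # every chain producing its head item has fired, so conditional
    # probabilities are measured against the head's final presence
    producers: dict[str, list[int]] = {}
    for i, c in enumerate(config.planted_chains):
        producers.setdefault(c.b, []).append(i)
    fired: set[int] = set()
    while len(fired) < len(config.planted_chains):
        progress = False
        for i, c in enumerate(config.planted_chains):
            if i in fired:
                continue
            if c.a in presence and all(j in fired for j in producers.get(c.a, [])):
                b = presence[c.a] & (rng.random(n) < c.p_ab)
                presence[c.b] = presence.get(c.b, np.zeros(n, bool)) | b
                fired.add(i)
                progress = True
        if not progress:
            raise ValueError("planted_chains contain a cyclic or dangling dependency")
    # terminals last, against the final intermediate presence
    for c in config.planted_chains:
        t = presence[c.b] & (rng.random(n) < c.p_bt)
        presence[c.terminal] = presence.get(c.terminal, np.zeros(n, bool)) | t

    width = len(str(n))
    doc_ids = np.array([f"PMID{i + 1:0{width}d}" for i in range(n)])
    docs: dict[str, set[str]] = {d: set() for d in doc_ids}
    for item, mask in presence.items():
        for idx in np.flatnonzero(mask):
            docs[doc_ids[idx]].add(item)

    edges = tuple(
        e for c in config.planted_chains for e in ((c.a, c.b), (c.b, c.terminal))
    )
    truth = PlantedTruth(
        specific_na=frozenset(na), specific_ha=frozenset(ha), chain_edges=edges
    )
    return TermIncidence(docs), truth


#: number of flagged terms planted per category; chosen so planted markers
#: clear the frequency gates (> 5 over all terms, > 2 over top-20, > 1 over
#: glucose terms) with one term to spare.
_N_IMMUNITY_BP = 8
_N_IMMUNITY_KEGG = 8
_N_GLUCOSE_BP = 3


def marker_gene_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    """The planted functional-marker subsets of the specific genes."""
    na, ha, _, _ = gene_ids(config)
    return na[: min(4, len(na))], ha[: min(2, len(ha))]


def generate_annotations(config: SimConfig) -> pd.DataFrame:
    """DAVID-like annotation table with category flags as data.

    Planted NA markers sit on > 5 immunity terms per source; planted HA
    markers sit on > 1 glucose BP term; background genes touch at most one
    flagged term.  Flagged terms receive small p-values so they fall inside
    the top-20 window.
    """
    config.validate()
    rng = _rng(config, _STREAM_ANNOTATIONS)
    na_markers, ha_markers = marker_gene_ids(config)
    na_all, ha_all, _, bg = gene_ids(config)

    rows = []
    term_no = 0

    def add_term(name, category, source, p, genes):
        nonlocal term_no
        term_no += 1
        rows.append(
            {
                "term_id": f"T{term_no:04d}",
                "term_name": name,
                "category": category,
                "source": source,
                "p_value": float(p),
                "genes": frozenset(genes),
            }
        )

    bg_pool = list(bg)
    immunity_names = [
        "response to cytokine",
        "cytokine-mediated signaling pathway",
        "immune response",
        "inflammatory response",
        "T cell activation",
        "leukocyte migration",
        "interleukin-6 production",
        "defense response",
    ]
    for i in range(_N_IMMUNITY_BP):
        category = "immunity" if i % 2 == 0 else "immunity_related"
        members = set(na_markers) | set(
            rng.choice(bg_pool, size=3, replace=False)
        )
        add_term(immunity_names[i], category, "BP", 10 ** rng.uniform(-6, -3), members)
    for i in range(_N_IMMUNITY_KEGG):
        category = "immunity" if i % 2 == 0 else "immunity_related"
        members = set(na_markers) | set(
            rng.choice(bg_pool, size=3, replace=False)
        )
        add_term(
            f"{immunity_names[i]} pathway",
            category,
            "KEGG",
            10 ** rng.uniform(-6, -3),
            members,
        )
    glucose_names = [
        "glucose metabolic process",
        "cellular response to glucose stimulus",
        "insulin secretion",
    ]
    for i in range(_N_GLUCOSE_BP):
        members = set(ha_markers) | set(
            rng.choice(bg_pool, size=3, replace=False)
        )
        add_term(glucose_names[i], "glucose", "BP", 10 ** rng.uniform(-6, -3), members)

    n_flagged = _N_IMMUNITY_BP + _N_IMMUNITY_KEGG + _N_GLUCOSE_BP
    # a background gene may sit on at most one flagged term: the flagged
    # members above are drawn from bg_pool, so remove any reused gene from
    # later flagged draws by construction — enforce via bookkeeping
    flagged_bg = set()
    for row in rows:
        extra = row["genes"] - set(na_markers) - set(ha_markers)
        dup = extra & flagged_bg
        if dup:
            row["genes"] = row["genes"] - dup
        flagged_bg |= extra
    for i in range(max(0, config.n_terms - n_flagged)):
        members = set(rng.choice(bg_pool, size=5, replace=False)) | set(
            rng.choice(list(na_all + ha_all), size=1)
        )
        source = "BP" if i % 2 == 0 else "KEGG"
        add_term(f"other process {i + 1}", "other", source, 10 ** rng.uniform(-4, 0), members)
    return pd.DataFrame(rows)


def generate_ppi(config: SimConfig) -> pd.DataFrame:
    """STRING-like undirected edge list connecting planted markers.

    Planted markers of each subtype form a connected ring; background genes
    receive sparse random edges.
    """
    config.validate()
    rng = _rng(config, _STREAM_PPI)
    na_markers, ha_markers = marker_gene_ids(config)
    _, _, _, bg = gene_ids(config)
    edges: set[tuple[str, str]] = set()
    rows = []

    def add_edge(a, b, evidence):
        if a == b:
            return
        key = tuple(sorted((a, b)))
        if key in edges:
            return
        edges.add(key)
        rows.append({"gene_a": key[0], "gene_b": key[1], "evidence": evidence})

    for group in (na_markers, ha_markers):
        for i in range(len(group)):
            add_edge(group[i], group[(i + 1) % len(group)], "experiment")
    n_random = 3 * config.n_genes // 100 + 10
    for _ in range(n_random):
        a, b = rng.choice(bg, size=2, replace=False)
        add_edge(a, b, "database")
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "evidence"])


def generate_drug_table(config: SimConfig) -> tuple[pd.DataFrame, DrugTruth]:
    """GRNdb-like drug–gene table with planted exclusive and shared drugs.

    Roughly a third of the drugs interact only with NA markers, a third only
    with HA markers, one drug bridges both (hence is excluded by the
    exclusivity rule), and the remainder hit background genes only.
    """
    config.validate()
    rng = _rng(config, _STREAM_DRUGS)
    na_markers, ha_markers = marker_gene_ids(config)
    _, _, _, bg = gene_ids(config)
    n = config.n_drugs
    n_na = max(1, n // 4)
    n_ha = max(1, n // 3)
    rows = []
    na_only, ha_only, shared = set(), set(), set()
    for i in range(n):
        drug = f"drug{i + 1:02d}"
        if i < n_na:
            targets = list(rng.choice(na_markers, size=min(2, len(na_markers)), replace=False))
            na_only.add(drug)
        elif i < n_na + n_ha:
            targets = list(rng.choice(ha_markers, size=min(2, len(ha_markers)), replace=False))
            ha_only.add(drug)
        elif i == n_na + n_ha:
            targets = [na_markers[0], ha_markers[0]]
            shared.add(drug)
        else:
            targets = list(rng.choice(bg, size=2, replace=False))
        for gene in targets:
            rows.append(
                {"drug": drug, "gene": gene, "score": float(np.round(rng.uniform(0.1, 1.0), 3))}
            )
    table = pd.DataFrame(rows, columns=["drug", "gene", "score"])
    return table, DrugTruth(frozenset(na_only), frozenset(ha_only), frozenset(shared))
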