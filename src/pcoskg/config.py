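"""Configuration objects for the simulator and the end-to-end pipeline.

Every threshold that the analysis applies downstream lives here with its
default value, so a run is fully described by one :class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


@dataclass(frozen=True)
class PlantedChain:
    """A conditional co-occurrence chain planted into the synthetic corpus.

    Documents contain the head item ``a`` with a base probability; given
    ``a``, the intermediate ``b`` appears with probability ``p_ab``; given
    ``b``, the ``terminal`` appears with probability ``p_bt``.  The chain is
    the ground truth that literature-rule mining is expected to recover as a
    directed path a -> b -> terminal.
    """

    a: str
    b: str
    terminal: str
    p_ab: float
    p_bt: float

    def validate(self) -> None:
        for p, name in ((self.p_ab, "p_ab"), (self.p_bt, "p_bt")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if not (self.a and self.b and self.terminal):
            raise ValueError("chain items must be non-empty strings")


#: Default background vocabulary of the synthetic corpus: MeSH-like terms with
#: per-document occurrence probabilities.  "PCOS" is deliberately frequent so
#: that gene–PCOS co-occurrence counts are informative, mirroring a corpus of
#: abstracts retrieved with a PCOS-centred query.
DEFAULT_BACKGROUND_ITEMS: dict[str, float] = {
    "PCOS": 0.30,
    "Insulin Resistance": 0.15,
    "Ovulation": 0.12,
    "Hyperandrogenism": 0.10,
    "Inflammation": 0.10,
    "Obesity": 0.08,
    "response to cytokine": 0.08,
    "cytokine-mediated signaling pathway": 0.05,
    "glucose metabolic process": 0.05,
    "Vitamin D": 0.04,
    "Gonadotropins": 0.03,
}


def _default_chains() -> tuple[PlantedChain, ...]:
    # Two NA-marker chains share the intermediate/terminal structure and one
    # gene-to-gene chain links them, so the assembled causal graph keeps every
    # chain node at total degree >= 2 and the paths survive pruning.
    return (
        PlantedChain("NAG01", "Interleukin-6", "female infertility", 0.5, 0.4),
        PlantedChain("NAG02", "Interleukin-6", "female infertility", 0.5, 0.4),
        PlantedChain("NAG01", "NAG02", "female infertility", 0.5, 0.4),
        PlantedChain("HAG01", "Calcium Signaling", "female infertility", 0.5, 0.4),
        PlantedChain("HAG02", "Calcium Signaling", "female infertility", 0.5, 0.4),
        PlantedChain("HAG01", "HAG02", "female infertility", 0.5, 0.4),
    )


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the study design: three groups (NM, NA PCOS, HA PCOS) of
    4 granulosa-cell samples each, tpm-scale expression with planted
    subtype-specific genes, a PubMed-like corpus with planted causal chains
    ending at "female infertility", DAVID-like annotation tables, a
    STRING-like PPI edge list and a GRNdb-like drug–gene table.
    """

    n_genes: int = 2000
    n_per_group: int = 4
    n_specific_na: int = 10
    n_specific_ha: int = 10
    n_specific_nm: int = 10
    fold: float = 4.0
    noise_sd: float = 0.2
    n_docs: int = 10_000
    planted_chains: Sequence[PlantedChain] = field(default_factory=_default_chains)
    n_terms: int = 40
    n_drugs: int = 12
    seed: int = 0
    # secondary knobs (not part of the headline design)
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.5
    chain_head_p: float = 0.20
    gene_doc_p: float = 0.10
    # latent per-document topics: gene mentions concentrate in their
    # subtype's topic, so NA- and HA-centred sub-corpora barely overlap
    na_topic_share: float = 0.35
    ha_topic_share: float = 0.35
    background_items: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_ITEMS)
    )
    n_filler_terms: int = 60
    filler_term_p: float = 0.02

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_per_group": self.n_per_group,
            "n_specific_na": self.n_specific_na,
            "n_specific_ha": self.n_specific_ha,
            "n_specific_nm": self.n_specific_nm,
            "n_docs": self.n_docs,
            "n_terms": self.n_terms,
            "n_drugs": self.n_drugs,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value}")
        if self.fold <= 0:
            raise ValueError(f"fold must be > 0, got {self.fold}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_specific_na + self.n_specific_ha + self.n_specific_nm > self.n_genes:
            raise ValueError("planted specific genes exceed n_genes")
        if not 0.0 < self.na_topic_share + self.ha_topic_share < 1.0:
            raise ValueError("topic shares must sum to a value in (0, 1)")
        if self.chain_head_p > min(self.na_topic_share, self.ha_topic_share):
            raise ValueError(
                "chain_head_p may not exceed the smaller topic share "
                "(the marginal head probability must fit inside its topic)"
            )
        for chain in self.planted_chains:
            chain.validate()
        for item, p in self.background_items.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"background probability for {item!r} outside [0, 1]")


@dataclass
class PipelineConfig:
    """All thresholds of the analysis chain, with the published defaults.

    tpm filter 0.1; differential p < 0.05 with fold change > 2 or < 0.5;
    cascade frequencies > 5 (all-terms window), > 2 (top-20 window) and > 1
    (glucose terms); co-occurrence > 0; classifier set sizes 10–50; WLAR cuts
    summed confidence > 0.6 and summed support > 30; literature cuts
    confidence > 0.1 and support > 0.001; terminal "female infertility";
    graph pruning at total degree < 2.
    """

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    tpm_threshold: float = 0.1
    p_cut: float = 0.05
    fc_hi: float = 2.0
    fc_lo: float = 0.5

    term_p_cut: float = 0.05
    top_k_terms: int = 20
    freq_all: int = 5
    freq_top: int = 2
    freq_glucose: int = 1
    min_cooccurrence: int = 1

    classifier_iterations: int = 20_000
    size_min: int = 10
    size_max: int = 50

    wlar_conf_cut: float = 0.6
    wlar_supp_cut: float = 30.0

    lit_conf_cut: float = 0.1
    lit_supp_cut: float = 0.001
    lit_support_mode: str = "fraction"
    chain_conf_cut: float = 0.1
    terminal: str = "female infertility"
    cooccur_query: str = "PCOS"

    min_degree: int = 2
    min_drug_marker_edges: int = 1

    def validate(self) -> None:
        self.sim.validate()
        if not 0.0 < self.p_cut < 1.0:
            raise ValueError("p_cut must lie in (0, 1)")
        if self.fc_hi <= self.fc_lo:
            raise ValueError("fc_hi must exceed fc_lo")
        if self.size_min < 1 or self.size_max < self.size_min:
            raise ValueError("invalid classifier size range")
        if self.lit_support_mode not in ("fraction", "count"):
            raise ValueError("lit_support_mode must be 'fraction' or 'count'")
        if self.min_degree < 0:
            raise ValueError("min_degree must be >= 0")


def _dataclass_from_mapping(cls, mapping):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML; absent keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_raw = raw.pop("sim", {})
    chains = sim_raw.pop("planted_chains", None)
    sim = _dataclass_from_mapping(SimConfig, sim_raw)
    if chains is not None:
        sim.planted_chains = tuple(PlantedChain(**c) for c in chains)
    cfg = _dataclass_from_mapping(PipelineConfig, raw)
    cfg.sim = sim
    cfg.validate()
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["sim"]["planted_chains"] = [dataclasses.asdict(c) for c in cfg.sim.planted_chains]
    return d
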