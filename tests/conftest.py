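"""Shared fixtures: small synthetic configurations and generated inputs."""

import numpy as np
import pandas as pd
import pytest

from pcoskg import simulate
from pcoskg.config import PlantedChain, SimConfig


@pytest.fixture
def small_config() -> SimConfig:
    """A fast three-group design: 200 genes, 4 samples per group."""
    return SimConfig(
        n_genes=200,
        n_per_group=4,
        n_specific_na=10,
        n_specific_ha=10,
        n_specific_nm=10,
        fold=4.0,
        noise_sd=0.2,
        n_docs=2000,
        n_filler_terms=10,
        seed=1,
    )


@pytest.fixture
def expression_data(small_config):
    return simulate.generate_expression(small_config)


@pytest.fixture
def toy_matrix() -> pd.DataFrame:
    """A tiny hand-written matrix: 4 genes x 6 samples."""
    return pd.DataFrame(
        {
            "s1": [1.0, 10.0, 0.0, 5.0],
            "s2": [2.0, 12.0, 0.0, 5.0],
            "s3": [3.0, 11.0, 0.1, 5.0],
            "s4": [4.0, 30.0, 0.0, 5.0],
            "s5": [5.0, 35.0, 0.2, 5.0],
            "s6": [6.0, 32.0, 0.0, 5.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )


@pytest.fixture
def toy_labels() -> pd.Series:
    return pd.Series(
        ["NM", "NM", "NM", "NA", "NA", "NA"],
        index=["s1", "s2", "s3", "s4", "s5", "s6"],
        name="group",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def single_chain_config(p_ab=0.5, p_bt=0.4, n_docs=10_000, seed=0) -> SimConfig:
    """Corpus config with one isolated planted chain for probability checks."""
    return SimConfig(
        n_docs=n_docs,
        seed=seed,
        planted_chains=(
            PlantedChain("geneX", "Ovulation", "female infertility", p_ab, p_bt),
        ),
        n_filler_terms=5,
    )
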