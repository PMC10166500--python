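import numpy as np
import pandas as pd
import pytest

from stagediv import CountMatrix, SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset with ground truth, shared across tests."""
    cfg = SimConfig(n_genes=400, seed=11)
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def small_cm(small_sim):
    return small_sim[0]


@pytest.fixture()
def tiny_cm():
    """Hand-built 4-gene x 4-sample matrix for exact-value checks."""
    counts = pd.DataFrame(
        {
            "a1": [10, 20, 30, 40],
            "a2": [10, 20, 30, 40],
            "b1": [10, 20, 30, 40],
            "b2": [10, 20, 30, 40],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    sample_meta = pd.DataFrame(
        {
            "population": ["NL", "NL", "ZI", "ZI"],
            "stage": ["early", "early", "early", "early"],
            "replicate": [1, 2, 1, 2],
        },
        index=counts.columns,
    )
    gene_meta = pd.DataFrame(
        {
            "biotype": ["protein_coding"] * 4,
            "arm": ["2L"] * 4,
            "start": [1, 1001, 2001, 3001],
            "end": [1000, 2000, 3000, 4000],
            "length": [1000, 1000, 1000, 1000],
        },
        index=counts.index,
    )
    return CountMatrix(counts=counts, sample_meta=sample_meta, gene_meta=gene_meta)
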