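import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from screendep import SimConfig, fit_model, simulate
from screendep.containers import ScreenDataset, TargetingMaps
from scipy import sparse

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_maps():
    """3 shRNAs: sh0->gA, sh1->gA+gB, sh2->gB; 2 distinct seeds."""
    G = sparse.csr_matrix(np.array([[1, 0], [1, 1], [0, 1]], dtype=float))
    B = sparse.csr_matrix(np.array([[1, 0], [1, 1], [0, 1]], dtype=float))
    return TargetingMaps(
        gene_matrix=G,
        seed_matrix=B,
        shrna_ids=["sh0", "sh1", "sh2"],
        gene_ids=["gA", "gB"],
        seed_ids=["s0", "s1"],
    )


@pytest.fixture
def tiny_data():
    """3 shRNAs x 2 screens (2 cell lines, 1 dataset), fully observed."""
    screens = pd.DataFrame(
        {"cell_line": ["c1", "c2"], "dataset": ["d1", "d1"]}
    )
    lfc = np.array([[-1.0, -0.5], [0.2, 0.1], [0.5, -0.2]])
    return ScreenDataset(
        lfc=lfc,
        mask=np.ones_like(lfc, dtype=bool),
        shrna_ids=["sh0", "sh1", "sh2"],
        screens=screens,
    )


SMALL_SIM = SimConfig(
    n_cell_lines=6,
    n_genes=24,
    shrnas_per_gene=4,
    n_seeds=30,
    fraction_common_essential=0.25,
    n_negative_controls=10,
    seed=11,
)


@pytest.fixture(scope="session")
def small_truth():
    return simulate(SMALL_SIM)


@pytest.fixture(scope="session")
def small_fit(small_truth):
    """One compact end-to-end fit shared by the inference tests."""
    return fit_model(small_truth.data, small_truth.maps, small_truth.controls)
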