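import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hspcflow import SimConfig, UmiMatrix, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """A small default-structure simulation shared across tests."""
    cfg = SimConfig(n_cells_per_condition=150, seed=11)
    matrix, truth = simulate_experiment(cfg)
    return cfg, matrix, truth


@pytest.fixture()
def tiny_matrix():
    """Hand-built 4-gene x 3-cell matrix with metadata."""
    counts = np.array([
        [3, 0, 5],
        [2, 0, 0],
        [5, 0, 1],
        [0, 0, 4],
    ])
    meta = pd.DataFrame(
        {"condition": ["A", "A", "B"]},
        index=pd.Index(["c1", "c2", "c3"], name="barcode"),
    )
    return UmiMatrix(counts=sp.csc_matrix(counts), genes=["g1", "g2", "g3", "g4"],
                     barcodes=["c1", "c2", "c3"], cell_meta=meta)
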