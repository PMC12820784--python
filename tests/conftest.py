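import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import cellcircuit as cc
from cellcircuit.pipeline import default_tissue_config


@pytest.fixture
def tiny_cells() -> cc.CellTable:
    df = pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3"],
            "x_um": [0.0, 10.0, 100.0],
            "y_um": [0.0, 0.0, 0.0],
            "cell_type": ["A", "B", "A"],
            "sample_id": ["s1", "s1", "s1"],
            "condition": ["control", "control", "control"],
        }
    )
    return cc.CellTable(df)


@pytest.fixture
def two_niche_tissue():
    cfg = cc.TissueConfig(
        niches=[
            cc.NicheSpec("left", (0, 0, 400, 400), {"t1": 0.8, "t2": 0.2}),
            cc.NicheSpec("right", (400, 0, 800, 400), {"t2": 0.2, "t3": 0.8}),
        ],
        n_samples={"control": 1},
        circuit=None,
        seed=7,
    )
    return cc.generate_tissue(cfg)


@pytest.fixture
def four_niche_config():
    def make(seed: int) -> cc.TissueConfig:
        cfg = default_tissue_config(seed, n_samples_per_condition=1)
        cfg.n_samples = {"control": 1}
        cfg.circuit = None
        cfg.seed = seed
        return cfg

    return make


def toy_expression() -> tuple[cc.ExpressionMatrix, np.ndarray]:
    """Three types x two cells each; equal library sizes (20 counts/cell) so
    normalized values are log1p(500*count) exactly."""
    genes = ["L1", "R1", "L2", "R2", "FILL"]
    types = np.array(["A", "A", "B", "B", "C", "C"])
    counts = np.array(
        [
            [10, 10, 0, 0, 0, 0],  # L1: A only
            [0, 0, 10, 10, 0, 0],  # R1: B only
            [0, 0, 5, 5, 10, 10],  # L2
            [10, 10, 5, 5, 0, 0],  # R2
            [0, 0, 0, 0, 0, 0],  # FILL: padding to equalize libraries
        ]
    )
    counts[4] = 20 - counts[:4].sum(axis=0)
    cells = [f"c{i}" for i in range(6)]
    return cc.ExpressionMatrix(genes, cells, sp.csr_matrix(counts)), types


@pytest.fixture
def toy_expr():
    return toy_expression()
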