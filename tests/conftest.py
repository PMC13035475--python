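import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mosaicpool import simdata
from mosaicpool.core import PooledExperiment


@pytest.fixture
def small_experiment():
    """Tiny deterministic experiment: 6 cells, 5 genes (one mitochondrial)."""
    counts = sp.csr_matrix(
        np.array(
            [
                [5, 1, 0, 2, 1],
                [0, 3, 1, 0, 4],
                [2, 2, 2, 2, 2],
                [9, 0, 0, 0, 1],
                [1, 1, 1, 1, 1],
                [0, 0, 3, 3, 0],
            ]
        )
    )
    cell_meta = pd.DataFrame(
        {
            "barcode": [f"bc{i}" for i in range(6)],
            "line_id": ["A", "A", "A", "B", "B", "B"],
            "condition": ["DMSO", "drug", "DMSO", "drug", "DMSO", "drug"],
            "dose": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
            "replicate": ["r1"] * 6,
        }
    )
    gene_meta = pd.DataFrame({"symbol": ["MT-CO1", "ACTB", "GAPDH", "TP53", "KRAS"]})
    return PooledExperiment(counts, cell_meta, gene_meta)


@pytest.fixture
def two_line_pool():
    """Simulated 2-line pool with vehicle and drug arms."""
    cfg = simdata.SimConfig(
        lines=[
            simdata.LineSpec("A", max_kill=0.9, log10_ic50=-1.0, hill=2.0),
            simdata.LineSpec("B"),
        ],
        conditions=[
            simdata.ConditionSpec("DMSO", 0.0, 1),
            simdata.ConditionSpec("drug", 1.0, 1),
        ],
        n_genes=80,
        pool_size=500,
        seed=7,
    )
    return simdata.simulate_pool(cfg)
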