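import numpy as np
import pandas as pd
import pytest

from lineagemap.sc_core import CellMatrix, normalize
from lineagemap.synthetic import LineageSpec, make_reference


@pytest.fixture(scope="session")
def small_reference():
    """Compact lineage-structured reference shared across tests."""
    spec = LineageSpec(seed=11, n_clusters_per_class=3, cells_per_cluster=(30, 50))
    return spec, make_reference(spec)


@pytest.fixture(scope="session")
def t1_dataset():
    """The 3-class x 25-cluster fingerprint recovery dataset (seed 1)."""
    spec = LineageSpec(
        classes=("MGE", "CGE_LGE", "excitatory"), n_clusters_per_class=25, seed=1
    )
    return make_reference(spec)


@pytest.fixture()
def tiny_matrix():
    """4 genes x 6 cells with hand-checkable counts."""
    counts = np.array([
        [1, 0, 3, 0, 2, 5],
        [2, 3, 0, 1, 0, 0],
        [0, 0, 4, 4, 1, 1],
        [1, 1, 1, 1, 1, 1],
    ])
    genes = ["G1", "G2", "G3", "G4"]
    cells = [f"c{i}" for i in range(6)]
    return CellMatrix(counts, genes, cells)
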