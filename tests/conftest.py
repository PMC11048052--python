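import numpy as np
import pytest

from gtadc.io import CellTypeLabels, ExpressionMatrix
from gtadc.simulate import SimulationConfig, simulate_reference


@pytest.fixture(scope="session")
def small_sim():
    """Small 3-type reference with planted markers, shared across tests."""
    cfg = SimulationConfig(
        k=3, cells_per_type=40, n_genes=300, markers_per_type=10, seed=7
    )
    ref, labels, marker_map = simulate_reference(cfg)
    return ref, labels, marker_map


@pytest.fixture()
def tiny_matrix():
    """4 cells × 3 genes with two cell types, hand-checkable."""
    values = np.array([
        [0.0, 2.0, 1.0],
        [2.0, 0.0, 1.0],
        [0.0, 4.0, 1.0],
        [4.0, 0.0, 1.0],
    ])
    Q = ExpressionMatrix(values, ["c1", "c2", "c3", "c4"], ["g1", "g2", "g3"])
    labels = CellTypeLabels(
        {"c1": "A", "c2": "B", "c3": "A", "c4": "B"}, ["A", "B"]
    )
    return Q, labels
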