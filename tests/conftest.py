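import numpy as np
import pytest

from kfrlsmda.containers import AssociationMatrix, SimilarityMatrix
from kfrlsmda.synthetic_data import SynthConfig, simulate_network


@pytest.fixture(scope="session")
def small_planted():
    """Small planted-block dataset shared across tests (30 x 12, 3 blocks)."""
    config = SynthConfig(
        n_m=30, n_d=12, n_blocks=3, p_in=0.5, p_out=0.02, sim_noise=0.1, seed=7
    )
    M, SM, SD, blocks = simulate_network(config)
    return M, SM, SD, blocks


@pytest.fixture
def toy_2x2():
    """The 2x2 instance used for hand-traceable end-to-end checks."""
    M = AssociationMatrix(
        np.array([[1.0, 0.0], [0.0, 1.0]]), ["m1", "m2"], ["d1", "d2"]
    )
    S = np.array([[1.0, 0.5], [0.5, 1.0]])
    SM = SimilarityMatrix(S, ["m1", "m2"], "miRNA_functional")
    SD = SimilarityMatrix(S, ["d1", "d2"], "disease_semantic")
    return M, SM, SD
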