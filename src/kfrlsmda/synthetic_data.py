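"""Synthetic miRNA-disease data with planted block structure.

The generator emulates the structural assumption underlying the
predictor — similar diseases tend to associate with functionally
similar miRNAs — by assigning miRNAs and diseases to shared latent
blocks.  A pair associates with probability ``p_in`` when the two
entities share a block and ``p_out`` otherwise, and the similarity
matrices are noisy indicators of block co-membership.  Because the
blocks couple the two axes, similarity genuinely predicts association,
so ranking-based evaluation on these data has signal to recover; with
``p_in == p_out`` the associations are structureless and provide a
null calibration.

A companion generator emits toy MeSH-style disease DAGs for exercising
the semantic-similarity code without any vocabulary download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AssociationMatrix, SimilarityMatrix
from .data_io import DagEdgeList

__all__ = ["SynthConfig", "simulate_network", "simulate_dags"]


@dataclass(frozen=True)
class SynthConfig:
    """Planted-block generator settings.

    Defaults give a 100 x 40 network with 5 blocks, dense within-block
    association (p_in=0.3) over a sparse background (p_out=0.01), and
    mild similarity noise — a small but structured stand-in for a real
    association database.
    """

    n_m: int = 100
    n_d: int = 40
    n_blocks: int = 5
    p_in: float = 0.3
    p_out: float = 0.01
    sim_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_m < 1 or self.n_d < 1:
            raise ValueError("n_m and n_d must be >= 1")
        if self.n_blocks < 1 or self.n_blocks > min(self.n_m, self.n_d):
            raise ValueError("n_blocks must be in [1, min(n_m, n_d)]")
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.sim_noise < 0:
            raise ValueError("sim_noise must be >= 0")


def _block_similarity(
    labels: np.ndarray, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Noisy block-membership indicator matrix: symmetric, unit diagonal."""
    base = (labels[:, None] == labels[None, :]).astype(float)
    if noise > 0:
        # draw the upper triangle and mirror so the noise stays uniform
        pert = np.zeros_like(base)
        iu = np.triu_indices(base.shape[0], k=1)
        pert[iu] = rng.uniform(-noise, noise, size=iu[0].size)
        pert = pert + pert.T
        base = base + pert
    np.fill_diagonal(base, 1.0)
    return np.clip(base, 0.0, 1.0)


def simulate_network(
    config: SynthConfig = SynthConfig(),
) -> tuple[AssociationMatrix, SimilarityMatrix, SimilarityMatrix, dict]:
    """Generate (associations, miRNA similarity, disease similarity, labels).

    miRNAs and diseases are assigned to blocks round-robin; the
    returned dict holds the block label of every entity.  Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m_blocks = np.arange(config.n_m) % config.n_blocks
    d_blocks = np.arange(config.n_d) % config.n_blocks
    same = m_blocks[:, None] == d_blocks[None, :]
    prob = np.where(same, config.p_in, config.p_out)
    values = (rng.random((config.n_m, config.n_d)) < prob).astype(float)

    mirna_ids = [f"mir-{i:04d}" for i in range(config.n_m)]
    disease_ids = [f"disease-{j:04d}" for j in range(config.n_d)]
    M = AssociationMatrix(values, mirna_ids, disease_ids)
    SM = SimilarityMatrix(
        _block_similarity(m_blocks, config.sim_noise, rng),
        mirna_ids,
        "miRNA_functional",
    )
    SD = SimilarityMatrix(
        _block_similarity(d_blocks, config.sim_noise, rng),
        disease_ids,
        "disease_semantic",
    )
    block_labels = {
        "mirna": dict(zip(mirna_ids, m_blocks.tolist())),
        "disease": dict(zip(disease_ids, d_blocks.tolist())),
    }
    return M, SM, SD, block_labels


def simulate_dags(
    n_diseases: int,
    depth: int = 3,
    branching: int = 2,
    shared_root_fraction: float = 0.5,
    seed: int = 0,
) -> DagEdgeList:
    """Generate toy tree-shaped disease DAGs over a shared vocabulary.

    Each disease term has ``branching`` parents at the first ancestor
    level; above that, each term has a single parent, up to ``depth``
    levels.  A disease drawn (with probability ``shared_root_fraction``)
    into the shared group uses a common ancestor vocabulary, so shared
    diseases have identical ancestor sets; other diseases use private
    terms and are pairwise disjoint.  Acyclic by construction.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if branching < 1:
        raise ValueError("branching must be >= 1")
    if not 0 <= shared_root_fraction <= 1:
        raise ValueError("shared_root_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dags: DagEdgeList = {}
    for idx in range(n_diseases):
        disease = f"disease-{idx:04d}"
        shared = rng.random() < shared_root_fraction
        prefix = "shared" if shared else disease
        edges: list[tuple[str, str]] = []
        level1 = [f"{prefix}-a1-{b}" for b in range(branching)]
        for term in level1:
            edges.append((disease, term))
        for b, term in enumerate(level1):
            child = term
            for lvl in range(2, depth + 1):
                parent = f"{prefix}-a{lvl}-{b}"
                edges.append((child, parent))
                child = parent
        dags[disease] = edges
    return dags
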