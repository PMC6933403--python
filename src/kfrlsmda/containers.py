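"""Core labeled-matrix containers shared by all pipeline stages.

The package works with three kinds of matrices:

* :class:`AssociationMatrix` — the binary bipartite adjacency ``M``
  (miRNA rows x disease columns) of known miRNA-disease associations.
* :class:`SimilarityMatrix` — square labeled similarity/kernel matrices
  (miRNA functional similarity, disease semantic similarity, Gaussian
  interaction-profile kernels, fused kernels).
* :class:`ScoreMatrix` — the predictor output ``F*`` with diseases as
  rows and miRNAs as columns; entry (i, j) scores the association of
  disease i with miRNA j.

Containers are thin dataclasses around ``numpy`` arrays plus ordered
label lists; they validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "ScoreMatrix",
    "SIMILARITY_ROLES",
]

#: Roles a SimilarityMatrix may play in the pipeline.  Symmetry and
#: nonnegativity are enforced for all of them; intermediate diffusion
#: states are plain ndarrays and therefore exempt.
SIMILARITY_ROLES = frozenset(
    {
        "miRNA_functional",
        "disease_semantic",
        "miRNA_GIP",
        "disease_GIP",
        "fused_miRNA",
        "fused_disease",
    }
)


def _check_unique(ids: Sequence[str], axis: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {axis} identifiers: {dupes[:5]}")
    return ids


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease adjacency matrix with identifier labels."""

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        n_m, n_d = self.values.shape
        if n_m < 1 or n_d < 1:
            raise ValueError("association matrix must be non-empty")
        if n_m != len(self.mirna_ids) or n_d != len(self.disease_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match labels "
                f"({len(self.mirna_ids)} miRNAs, {len(self.disease_ids)} diseases)"
            )
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("association matrix entries must be exactly 0 or 1")
        self.values = self.values.astype(np.float64)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_associations(self) -> int:
        """Number of distinct known associations (ones in the matrix)."""
        return int(self.values.sum())

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.mirna_ids), list(self.disease_ids)
        )

    def known_pairs(self) -> list[tuple[int, int]]:
        """Indices (miRNA row, disease column) of all known associations."""
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass
class SimilarityMatrix:
    """Square labeled similarity matrix with a declared pipeline role."""

    values: np.ndarray
    ids: list[str]
    role: str = field(default="miRNA_functional")

    #: absolute tolerance used when validating symmetry
    SYMMETRY_TOL = 1e-8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.role not in SIMILARITY_ROLES:
            raise ValueError(f"unknown similarity role {self.role!r}")
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")
        self.ids = _check_unique(self.ids, "similarity")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("id list length does not match matrix dimension")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity matrix contains non-finite entries")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > self.SYMMETRY_TOL:
            raise ValueError(
                f"similarity matrix for role {self.role!r} is asymmetric "
                f"(max |S - S^T| = {asym:.3g})"
            )
        # squash numerical asymmetry below tolerance
        self.values = (self.values + self.values.T) / 2.0
        if (self.values < 0).any():
            raise ValueError("similarity matrix entries must be >= 0")

    @property
    def n(self) -> int:
        return len(self.ids)

    def reindex(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Return a copy reordered to ``ids`` (must be a subset of ours)."""
        ids = [str(i) for i in ids]
        pos = {label: k for k, label in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"ids missing from similarity matrix: {missing[:5]}")
        idx = np.array([pos[i] for i in ids])
        return SimilarityMatrix(self.values[np.ix_(idx, idx)], ids, self.role)


@dataclass
class ScoreMatrix:
    """Predicted association scores, diseases as rows and miRNAs as columns."""

    values: np.ndarray
    disease_ids: list[str]
    mirna_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("score matrix must be 2-dimensional")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        if self.values.shape != (len(self.disease_ids), len(self.mirna_ids)):
            raise ValueError(
                f"score matrix shape {self.values.shape} does not match labels"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("score matrix contains non-finite entries")
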