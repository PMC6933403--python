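"""Gaussian interaction-profile (GIP) kernel similarity.

The interaction profile of a disease is the binary column of the
association matrix recording which miRNAs it is linked to (and
symmetrically for miRNAs).  Two entities are similar when their
profiles are close:

    K(u, v) = exp(-gamma * ||IP(u) - IP(v)||^2)

with the bandwidth normalized by the mean squared profile norm,

    gamma = gamma' / (mean_u ||IP(u)||^2)

so that the kernel scale adapts to the overall density of known
associations.  gamma' defaults to 1 in both spaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .containers import AssociationMatrix, SimilarityMatrix

__all__ = ["GipParams", "gip_bandwidth", "gip_kernel"]

_AXES = ("disease", "miRNA")


@dataclass(frozen=True)
class GipParams:
    """Bandwidth scale parameters gamma' for the two spaces."""

    gamma_prime_d: float = 1.0
    gamma_prime_m: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_prime_d <= 0 or self.gamma_prime_m <= 0:
            raise ValueError("bandwidth scales must be positive")


def _profiles(M: AssociationMatrix, axis: str) -> np.ndarray:
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {_AXES}, got {axis!r}")
    # disease profiles are columns of M, miRNA profiles are rows
    return M.values.T if axis == "disease" else M.values


def gip_bandwidth(
    M: AssociationMatrix, axis: str, params: GipParams = GipParams()
) -> float:
    """Normalized kernel bandwidth gamma for the chosen axis."""
    profiles = _profiles(M, axis)
    mean_sq_norm = float((profiles**2).sum(axis=1).mean())
    if mean_sq_norm == 0:
        raise ValueError(
            "association matrix has no known associations; "
            "GIP bandwidth is undefined"
        )
    gamma_prime = params.gamma_prime_d if axis == "disease" else params.gamma_prime_m
    return gamma_prime / mean_sq_norm


def gip_kernel(
    M: AssociationMatrix, axis: str, params: GipParams = GipParams()
) -> SimilarityMatrix:
    """GIP kernel similarity matrix for diseases or miRNAs.

    Entities whose profile is all-zero (possible when associations have
    been masked for cross-validation) are kept; their pairwise kernel
    values follow from the zero profile.
    """
    gamma = gip_bandwidth(M, axis, params)
    profiles = _profiles(M, axis)
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-gamma * sq_dists)
    ids = M.disease_ids if axis == "disease" else M.mirna_ids
    role = "disease_GIP" if axis == "disease" else "miRNA_GIP"
    return SimilarityMatrix(values, ids, role)
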