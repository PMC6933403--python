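"""Two-view nonlinear kernel fusion by cross-diffusion.

In each space (miRNA or disease) two similarity sources are available:
a biological similarity matrix (functional or semantic) and a GIP
kernel computed from the association matrix.  Rather than averaging
them, the two views are fused SNF-style:

1. the biological similarity is lifted towards positive
   semi-definiteness by adding ``epsilon * I``;
2. each view is row-normalized and symmetrized into a status matrix
   ``P = (R + R^T) / 2``;
3. a sparse local transition matrix ``L`` keeps, per row, only the
   ``k`` largest off-diagonal similarities, renormalized to sum 1;
4. for ``t`` iterations each status matrix is diffused through the
   *other* view's previous state,

       P1 <- L1 P2 L1^T + I,    P2 <- L2 P1 L2^T + I

   (both updates use the previous states; L1, L2 stay fixed);
5. the final states are averaged, row-normalized, and symmetrized via
   ``K <- (K + K^T + I) / 2``.

The local matrices restrict diffusion to each entity's nearest
neighbours, which suppresses noisy weak similarities while the
cross-view updates exchange information between the two sources.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SimilarityMatrix

__all__ = [
    "FusionParams",
    "psd_lift",
    "normalize_symmetrize",
    "local_matrix",
    "cross_diffuse",
    "finalize_fusion",
    "fuse_space",
]


@dataclass(frozen=True)
class FusionParams:
    """Cross-diffusion parameters.

    epsilon lifts the raw similarity towards PSD; k_neighbors is the
    local neighbourhood size; iterations the number of diffusion steps.
    """

    epsilon: float = 0.1
    k_neighbors: int = 4
    iterations: int = 2

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def psd_lift(S: np.ndarray, epsilon: float) -> np.ndarray:
    """Add epsilon on the diagonal: S + epsilon * I."""
    S = np.asarray(S, dtype=float)
    return S + epsilon * np.eye(S.shape[0])


def normalize_symmetrize(K: np.ndarray) -> np.ndarray:
    """Row-normalize, then symmetrize by averaging with the transpose."""
    K = np.asarray(K, dtype=float)
    sums = K.sum(axis=1)
    bad = np.nonzero(sums <= 0)[0]
    if bad.size:
        raise ValueError(f"row(s) {bad.tolist()[:5]} have non-positive sum")
    R = K / sums[:, None]
    return (R + R.T) / 2.0


def local_matrix(P: np.ndarray, k: int) -> np.ndarray:
    """Row-stochastic k-nearest-neighbour transition matrix.

    Row i keeps the k largest off-diagonal entries of P (self excluded,
    ties at the k-th rank broken by lower column index) renormalized to
    sum 1; everything else, including the diagonal, is zero.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if k > n - 1:
        raise ValueError(f"k={k} exceeds the {n - 1} available neighbours")
    L = np.zeros_like(P)
    for i in range(n):
        row = P[i].copy()
        row[i] = -np.inf  # exclude self
        # stable sort on (-value, index): largest first, lower index wins ties
        order = np.lexsort((np.arange(n), -row))
        nbrs = order[:k]
        mass = P[i, nbrs].sum()
        if mass <= 0:
            raise ValueError(
                f"row {i}: top-{k} neighbour similarity mass is zero"
            )
        L[i, nbrs] = P[i, nbrs] / mass
    return L


def cross_diffuse(
    P1: np.ndarray,
    P2: np.ndarray,
    L1: np.ndarray,
    L2: np.ndarray,
    iterations: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the two-view diffusion for the given number of iterations.

    Each iteration updates both states simultaneously from the other
    view's previous state and then adds the identity; the transition
    matrices are held fixed throughout.
    """
    P1 = np.asarray(P1, dtype=float)
    P2 = np.asarray(P2, dtype=float)
    eye = np.eye(P1.shape[0])
    for _ in range(iterations):
        P1, P2 = L1 @ P2 @ L1.T + eye, L2 @ P1 @ L2.T + eye
    return P1, P2


def finalize_fusion(P1_t: np.ndarray, P2_t: np.ndarray) -> np.ndarray:
    """Average the final states, row-normalize, apply (K + K^T + I)/2."""
    K = (np.asarray(P1_t, dtype=float) + np.asarray(P2_t, dtype=float)) / 2.0
    sums = K.sum(axis=1)
    bad = np.nonzero(sums <= 0)[0]
    if bad.size:
        raise ValueError(f"row(s) {bad.tolist()[:5]} have non-positive sum")
    K = K / sums[:, None]
    return (K + K.T + np.eye(K.shape[0])) / 2.0


def fuse_space(
    S: SimilarityMatrix, K_gip: SimilarityMatrix, params: FusionParams = FusionParams()
) -> SimilarityMatrix:
    """Fuse a biological similarity with the GIP kernel of the same space."""
    if S.ids != K_gip.ids:
        raise ValueError("similarity and GIP kernel ids differ or are reordered")
    fused = fuse_arrays(S.values, K_gip.values, params)
    role = "fused_miRNA" if S.role.startswith("miRNA") else "fused_disease"
    return SimilarityMatrix(fused, list(S.ids), role)


def fuse_arrays(
    S: np.ndarray, K_gip: np.ndarray, params: FusionParams = FusionParams()
) -> np.ndarray:
    """Label-free fusion core used by :func:`fuse_space` and the CV loops."""
    P1 = normalize_symmetrize(psd_lift(S, params.epsilon))
    P2 = normalize_symmetrize(K_gip)
    L1 = local_matrix(P1, params.k_neighbors)
    L2 = local_matrix(P2, params.k_neighbors)
    P1_t, P2_t = cross_diffuse(P1, P2, L1, L2, params.iterations)
    return finalize_fusion(P1_t, P2_t)
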