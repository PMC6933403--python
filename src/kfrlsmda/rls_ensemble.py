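"""Regularized least-squares scoring and the two-space ensemble.

Given a fused kernel ``K`` and a label matrix ``A``, the RLS classifier
has the closed form of kernel ridge regression,

    F = K (K + eta I)^{-1} A

which shrinks towards the observed labels as eta -> 0.  A classifier is
fit in each space — miRNA space (K = fused miRNA kernel, A = M) and
disease space (K = fused disease kernel, A = M^T) — and the two score
matrices are combined by a weighted average

    F* = alpha * F_M^T + (1 - alpha) * F_D

yielding a disease x miRNA score matrix.  Defaults eta_M = eta_D = 0.3
and alpha = 0.1 follow the usual practice for this family of models.

Note on the label matrix: with an n_m x n_m kernel the label matrix in
the miRNA space must have n_m rows, i.e. A = M (not M^T); the disease
space symmetrically uses A = M^T.  This is the only dimensionally
consistent arrangement and is what makes the ensemble shapes work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .containers import AssociationMatrix, ScoreMatrix, SimilarityMatrix
from .gip_kernel import GipParams
from .kernel_fusion import FusionParams, fuse_arrays

__all__ = ["ModelParams", "rls_scores", "ensemble", "kfrlsmda_predict"]


@dataclass(frozen=True)
class ModelParams:
    """RLS trade-offs (eta) and ensemble weight (alpha)."""

    eta_m: float = 0.3
    eta_d: float = 0.3
    alpha: float = 0.1

    def __post_init__(self) -> None:
        if self.eta_m < 0 or self.eta_d < 0:
            raise ValueError("eta_m and eta_d must be >= 0")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")


def rls_scores(K: np.ndarray, A: np.ndarray, eta: float) -> np.ndarray:
    """Closed-form RLS scores K (K + eta I)^{-1} A."""
    K = np.asarray(K, dtype=float)
    A = np.asarray(A, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n):
        raise ValueError("kernel must be square")
    if A.shape[0] != n:
        raise ValueError(
            f"label matrix has {A.shape[0]} rows, kernel is {n}x{n}"
        )
    try:
        # solve (K + eta I)^T X^T = K^T, i.e. X = K (K + eta I)^{-1}
        X = scipy.linalg.solve(K + eta * np.eye(n), K, assume_a="gen").T
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"(K + eta I) is singular with eta={eta}; increase eta"
        ) from err
    return X @ A


def ensemble(F_M: np.ndarray, F_D: np.ndarray, alpha: float) -> np.ndarray:
    """Weighted average F* = alpha F_M^T + (1 - alpha) F_D (disease x miRNA)."""
    F_M = np.asarray(F_M, dtype=float)
    F_D = np.asarray(F_D, dtype=float)
    if F_M.T.shape != F_D.shape:
        raise ValueError(
            f"shapes incompatible: F_M {F_M.shape} vs F_D {F_D.shape}"
        )
    return alpha * F_M.T + (1 - alpha) * F_D


def predict_scores(
    M_values: np.ndarray,
    SM_values: np.ndarray,
    SD_values: np.ndarray,
    fusion: FusionParams = FusionParams(),
    gip: GipParams = GipParams(),
    model: ModelParams = ModelParams(),
) -> np.ndarray:
    """Label-free prediction core: association matrix in, scores out.

    Used directly by the cross-validation loops, which re-run it many
    times on masked copies of the association matrix.
    """
    from scipy.spatial.distance import pdist, squareform

    M_values = np.asarray(M_values, dtype=float)
    total = M_values.sum()
    if total == 0:
        raise ValueError("association matrix has no known associations")
    # GIP kernels in both spaces
    gamma_m = gip.gamma_prime_m / float((M_values**2).sum(axis=1).mean())
    gamma_d = gip.gamma_prime_d / float((M_values**2).sum(axis=0).mean())
    KM = np.exp(-gamma_m * squareform(pdist(M_values, "sqeuclidean")))
    KD = np.exp(-gamma_d * squareform(pdist(M_values.T, "sqeuclidean")))
    # cross-diffusion fusion in both spaces
    K_kf_M = fuse_arrays(SM_values, KM, fusion)
    K_kf_D = fuse_arrays(SD_values, KD, fusion)
    # RLS classifiers and ensemble
    F_M = rls_scores(K_kf_M, M_values, model.eta_m)
    F_D = rls_scores(K_kf_D, M_values.T, model.eta_d)
    return ensemble(F_M, F_D, model.alpha)


def kfrlsmda_predict(
    M: AssociationMatrix,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    fusion: FusionParams = FusionParams(),
    gip: GipParams = GipParams(),
    model: ModelParams = ModelParams(),
) -> ScoreMatrix:
    """End-to-end prediction of miRNA-disease association scores.

    Pipeline: GIP kernels from M in both spaces, cross-diffusion fusion
    of (SM, KM) and (SD, KD), RLS classifiers in both spaces, weighted
    ensemble.  Fully deterministic.
    """
    if SM.ids != M.mirna_ids:
        raise ValueError(
            "miRNA similarity ids do not match association matrix miRNAs; "
            f"first mismatch near {_first_mismatch(SM.ids, M.mirna_ids)!r}"
        )
    if SD.ids != M.disease_ids:
        raise ValueError(
            "disease similarity ids do not match association matrix diseases; "
            f"first mismatch near {_first_mismatch(SD.ids, M.disease_ids)!r}"
        )
    values = predict_scores(M.values, SM.values, SD.values, fusion, gip, model)
    return ScoreMatrix(values, list(M.disease_ids), list(M.mirna_ids))


def _first_mismatch(a: list[str], b: list[str]) -> str:
    for x, y in zip(a, b):
        if x != y:
            return f"{x} vs {y}"
    return f"length {len(a)} vs {len(b)}"
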