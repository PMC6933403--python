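"""Cross-validation protocols and rank-based ROC/AUC.

Three evaluation schemes are provided, all built on the same ranking
idea: a held-out known association is scored by a model trained without
it, and its score is ranked against the scores of *candidate samples* —
miRNA-disease pairs with no known association in the full database.

* global LOOCV — each known association is held out in turn and ranked
  against all candidate pairs across all diseases;
* local LOOCV — as global, but the held-out pair is ranked only against
  the candidate miRNAs of its own disease;
* repeated k-fold CV — known associations are randomly partitioned into
  k near-equal subsets; each subset is masked in turn and its pairs are
  ranked globally; the whole procedure is repeated with fresh random
  partitions and the AUC mean and sample standard deviation across
  repeats are reported.

The AUC is the rank-sum (Mann-Whitney) statistic: the mean, over test
samples, of the fraction of candidates scored strictly lower plus half
the fraction tied.  The ROC curve is the exact staircase whose
trapezoidal area equals this statistic.

By default the GIP kernels (and hence the whole model) are recomputed
from the masked association matrix in every fold, so no information
about held-out pairs leaks through the interaction profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .containers import AssociationMatrix, SimilarityMatrix
from .gip_kernel import GipParams
from .kernel_fusion import FusionParams
from .rls_ensemble import ModelParams, predict_scores

__all__ = [
    "CVConfig",
    "CVResult",
    "ranking_auc",
    "global_loocv",
    "local_loocv",
    "kfold_cv",
    "disease_pair_correlations",
    "score_group_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings.

    recompute_kernels controls whether the GIP kernels and downstream
    model are refit on the masked matrix in every fold (default) or
    computed once from the full data.
    """

    mode: str = "global_loocv"
    folds: int = 5
    repeats: int = 100
    seed: int = 0
    recompute_kernels: bool = True

    def __post_init__(self) -> None:
        if self.mode not in {"global_loocv", "local_loocv", "kfold"}:
            raise ValueError(f"unknown CV mode {self.mode!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class CVResult:
    """Per-test ranks, ROC staircase, and AUC summaries."""

    mode: str
    per_test_rank: list[tuple[str, str, float, int]]
    roc: list[tuple[float, float]]
    auc: float
    per_repeat_auc: list[float] = field(default_factory=list)
    auc_mean: float | None = None
    auc_sd: float | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {
            "mode": self.mode,
            "auc": self.auc,
            "n_test": len(self.per_test_rank),
            "roc": [list(p) for p in self.roc],
            "per_test_rank": [list(r) for r in self.per_test_rank],
        }
        if self.per_repeat_auc:
            out["per_repeat_auc"] = self.per_repeat_auc
            out["auc_mean"] = self.auc_mean
            out["auc_sd"] = self.auc_sd
        if self.seed is not None:
            out["seed"] = self.seed
        return out


def _percentile(score: float, candidates: np.ndarray) -> float:
    """Fraction of candidates strictly below ``score`` plus half the ties."""
    lower = np.count_nonzero(candidates < score)
    ties = np.count_nonzero(candidates == score)
    return (lower + 0.5 * ties) / candidates.size


def ranking_auc(test_scores, candidate_scores) -> float:
    """Rank-sum AUC of test scores against a common candidate pool."""
    tests = np.asarray(test_scores, dtype=float)
    cands = np.asarray(candidate_scores, dtype=float)
    if tests.size == 0 or cands.size == 0:
        raise ValueError("test and candidate score lists must be non-empty")
    return float(np.mean([_percentile(s, cands) for s in tests]))


def roc_from_percentiles(percentiles) -> list[tuple[float, float]]:
    """Exact ROC staircase for per-test candidate percentiles.

    Each test contributes the fraction ``f = 1 - u`` of candidates
    ranked at or above it; sweeping the rank threshold over [0, 1]
    gives FPR = threshold and TPR = fraction of tests with f <= FPR.
    Corner points are duplicated so the trapezoidal area equals the
    mean percentile exactly.
    """
    u = np.asarray(percentiles, dtype=float)
    f = np.sort(1.0 - u)
    n = f.size
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    prev_tpr = 0.0
    values, counts = np.unique(f, return_counts=True)
    cum = np.cumsum(counts)
    for v, c in zip(values, cum):
        x = float(min(max(v, 0.0), 1.0))
        points.append((x, prev_tpr))
        prev_tpr = float(c) / n
        points.append((x, prev_tpr))
    points.append((1.0, 1.0))
    return points


def _scores_for_mask(
    M: AssociationMatrix,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    mask_pairs: list[tuple[int, int]],
    fusion: FusionParams,
    gip: GipParams,
    model: ModelParams,
) -> np.ndarray:
    """Score matrix (disease x miRNA) after zeroing the held-out pairs."""
    work = M.values.copy()
    for i, j in mask_pairs:
        work[i, j] = 0.0
    return predict_scores(work, SM.values, SD.values, fusion, gip, model)


def global_loocv(
    M: AssociationMatrix,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    fusion: FusionParams = FusionParams(),
    gip: GipParams = GipParams(),
    model: ModelParams = ModelParams(),
    config: CVConfig = CVConfig(mode="global_loocv"),
) -> CVResult:
    """Leave each known association out; rank it against all candidates."""
    positives = M.known_pairs()
    if len(positives) < 2:
        raise ValueError("global LOOCV requires at least 2 known associations")
    cand_mask = M.values.T == 0  # disease x miRNA, candidates of the FULL matrix
    full_scores = None
    if not config.recompute_kernels:
        full_scores = _scores_for_mask(M, SM, SD, [], fusion, gip, model)

    percentiles, records = [], []
    for i, j in positives:
        if config.recompute_kernels:
            scores = _scores_for_mask(M, SM, SD, [(i, j)], fusion, gip, model)
        else:
            scores = full_scores
        cands = scores[cand_mask]
        s = scores[j, i]
        u = _percentile(s, cands)
        percentiles.append(u)
        rank = 1 + np.count_nonzero(cands > s) + 0.5 * np.count_nonzero(cands == s)
        records.append((M.mirna_ids[i], M.disease_ids[j], float(rank), int(cands.size)))
    auc = float(np.mean(percentiles))
    return CVResult(
        mode="global_loocv",
        per_test_rank=records,
        roc=roc_from_percentiles(percentiles),
        auc=auc,
    )


def local_loocv(
    M: AssociationMatrix,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    fusion: FusionParams = FusionParams(),
    gip: GipParams = GipParams(),
    model: ModelParams = ModelParams(),
    config: CVConfig = CVConfig(mode="local_loocv"),
) -> CVResult:
    """As global LOOCV, but rank only within the held-out pair's disease."""
    positives = M.known_pairs()
    if len(positives) < 2:
        raise ValueError("local LOOCV requires at least 2 known associations")
    full_scores = None
    if not config.recompute_kernels:
        full_scores = _scores_for_mask(M, SM, SD, [], fusion, gip, model)

    percentiles, records = [], []
    for i, j in positives:
        cand_rows = np.nonzero(M.values[:, j] == 0)[0]
        if cand_rows.size == 0:
            logger.warning(
                "disease %s has no candidate miRNAs; test sample (%s, %s) skipped",
                M.disease_ids[j], M.mirna_ids[i], M.disease_ids[j],
            )
            continue
        if config.recompute_kernels:
            scores = _scores_for_mask(M, SM, SD, [(i, j)], fusion, gip, model)
        else:
            scores = full_scores
        cands = scores[j, cand_rows]
        s = scores[j, i]
        u = _percentile(s, cands)
        percentiles.append(u)
        rank = 1 + np.count_nonzero(cands > s) + 0.5 * np.count_nonzero(cands == s)
        records.append((M.mirna_ids[i], M.disease_ids[j], float(rank), int(cands.size)))
    auc = float(np.mean(percentiles))
    return CVResult(
        mode="local_loocv",
        per_test_rank=records,
        roc=roc_from_percentiles(percentiles),
        auc=auc,
    )


def kfold_cv(
    M: AssociationMatrix,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    fusion: FusionParams = FusionParams(),
    gip: GipParams = GipParams(),
    model: ModelParams = ModelParams(),
    config: CVConfig = CVConfig(mode="kfold"),
) -> CVResult:
    """Repeated k-fold CV with global candidate ranking per fold."""
    positives = M.known_pairs()
    if config.folds > len(positives):
        raise ValueError(
            f"folds={config.folds} exceeds the {len(positives)} known associations"
        )
    cand_mask = M.values.T == 0
    per_repeat_auc: list[float] = []
    all_percentiles: list[float] = []
    records: list[tuple[str, str, float, int]] = []
    for r in range(config.repeats):
        rng = np.random.default_rng(config.seed + r)
        order = rng.permutation(len(positives))
        fold_assign = np.array_split(order, config.folds)
        repeat_percentiles = []
        for fold in fold_assign:
            held = [positives[t] for t in fold]
            scores = _scores_for_mask(M, SM, SD, held, fusion, gip, model)
            cands = scores[cand_mask]
            for i, j in held:
                s = scores[j, i]
                u = _percentile(s, cands)
                repeat_percentiles.append(u)
                if r == 0:
                    rank = (
                        1
                        + np.count_nonzero(cands > s)
                        + 0.5 * np.count_nonzero(cands == s)
                    )
                    records.append(
                        (M.mirna_ids[i], M.disease_ids[j], float(rank), int(cands.size))
                    )
        per_repeat_auc.append(float(np.mean(repeat_percentiles)))
        all_percentiles.extend(repeat_percentiles)
    auc_mean = float(np.mean(per_repeat_auc))
    auc_sd = float(np.std(per_repeat_auc, ddof=1)) if len(per_repeat_auc) > 1 else 0.0
    return CVResult(
        mode="kfold",
        per_test_rank=records,
        roc=roc_from_percentiles(all_percentiles),
        auc=auc_mean,
        per_repeat_auc=per_repeat_auc,
        auc_mean=auc_mean,
        auc_sd=auc_sd,
        seed=config.seed,
    )


def disease_pair_correlations(
    M: AssociationMatrix,
) -> list[tuple[str, str, float | None]]:
    """Pearson correlation of miRNA profiles for every unordered disease pair.

    Diseases whose profile has zero variance produce an undefined
    correlation, recorded as None.
    """
    n_d = M.n_diseases
    if n_d < 2:
        raise ValueError("need at least two diseases")
    X = M.values  # n_m x n_d; columns are disease profiles
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    out: list[tuple[str, str, float | None]] = []
    for a in range(n_d):
        for b in range(a + 1, n_d):
            v = C[a, b]
            out.append(
                (M.disease_ids[a], M.disease_ids[b], None if np.isnan(v) else float(v))
            )
    return out


def score_group_test(
    scores_confirmed, scores_unconfirmed
) -> tuple[float, float, float, float]:
    """Two-sided Wilcoxon rank-sum test between two score groups.

    Returns (rank-sum statistic W of the first group, two-sided
    p-value, mean of first group, mean of second group).  The p-value
    uses the exact null distribution when both groups are small and
    tie-free, and the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(scores_confirmed, dtype=float)
    y = np.asarray(scores_unconfirmed, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both score groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(combined)
    W = float(ranks[: x.size].sum())
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return W, float(res.pvalue), float(x.mean()), float(y.mean())
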