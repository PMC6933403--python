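# Methods

## Model

`kfrlsmda` predicts miRNA–disease associations under one structural
assumption: similar diseases tend to associate with functionally
similar miRNAs. Three inputs carry that structure — the binary
association matrix `M` (miRNA rows × disease columns), a miRNA
functional similarity `SM`, and a disease semantic similarity `SD` —
and two derived Gaussian interaction-profile (GIP) kernels `KM`, `KD`
re-express `M` itself as similarity. The pipeline is deterministic
end to end: GIP kernels → per-space cross-diffusion fusion → closed-form
regularized least-squares (RLS) scoring → weighted ensemble.

### Disease semantic similarity

Each disease is a DAG of its own MeSH-style term plus ancestors, with
edges stored child→parent. The term contribution recursion assigns 1
to the disease's own term and `δ × max over children` elsewhere, where
"children of d" are DAG-internal nodes one level closer to the
disease; multi-path terms take the max, not the sum. The similarity of
two diseases is the contribution mass on shared terms divided by the
sum of the two semantic values, which lies in [0, 1]. Terms not
reachable from the disease term are not ancestors; they are dropped
with a warning rather than an error, since a stray edge row should not
invalidate an otherwise well-formed DAG. Users with a precomputed `SD`
matrix can bypass this module entirely — both entry points are
supported everywhere a disease similarity is consumed.

### GIP kernels

The bandwidth is normalized by the mean squared profile norm, so the
kernel adapts to association density; the scale parameters γ'
(default 1 in both spaces, exposed in the CLI) are the only knobs. An
all-zero association matrix leaves the bandwidth undefined and raises.
Entities whose profile becomes all-zero after cross-validation masking
are kept and scored normally — dropping them would silently change the
candidate set between folds.

### Cross-diffusion fusion

Per space, the biological similarity and the GIP kernel are fused
nonlinearly rather than averaged. Numerical choices, in the order they
bind:

- ε = 0.1 is added to the raw similarity diagonal before
  normalization (a PSD lift; the GIP view is already a Gaussian kernel
  and is not lifted).
- Status matrices are the symmetrized row-normalizations
  `P = (R + Rᵀ)/2`; a zero-sum row is an error naming the row, since
  it means an entity with no similarity mass at all.
- The k-NN transition matrices (k = 4) exclude self, zero the
  diagonal, renormalize the kept entries, and break ties at the k-th
  rank by lower column index. Tie-breaking matters in practice: GIP
  kernels of binary profiles take discretized values, so exact ties at
  the neighbourhood boundary are common. The choice is deterministic
  but not permutation-equivariant when a boundary tie fires; the
  property tests therefore verify equivariance on instances checked to
  be boundary-tie-free.
- Two diffusion iterations (t = 2), both views updated simultaneously
  from the other view's previous state, identity added after every
  iteration including the last; `L1`, `L2` are computed once from the
  initial views and frozen.
- Finalization: elementwise mean of the two states, row-normalization,
  then `K ← (K + Kᵀ + I)/2`. Because row-normalization is
  scale-invariant, mean versus sum of the two states is provably
  irrelevant here (pinned by a regression test). The identity added at
  each step makes the fused kernels diagonally dominant, which bounds
  how much smoothing the RLS stage can perform — see "Limitations".

### RLS scoring and ensemble

`F = K (K + ηI)⁻¹ A` in each space, with `A = M` against the miRNA
kernel and `A = Mᵀ` against the disease kernel — the only
dimensionally consistent arrangement, matching the predecessor models
in this family. η_M = η_D = 0.3 trades data fit against kernel-norm
regularization; as η → 0 the scores reproduce the labels exactly
(tested). The ensemble weight α = 0.1 leans on the disease-space
classifier; an α grid search against CV AUC can be run by scoring at
several α values (the ensemble is affine in α, also tested). The
linear solve uses `scipy.linalg.solve` rather than an explicit
inverse; a singular `(K + ηI)` raises with the advice to increase η.

## Evaluation protocols

All protocols rank a held-out known association against *candidate
samples* — pairs unknown in the **full** association matrix (held-out
positives are never counted as negatives). Ranks use midranks for
ties, making the AUC the Mann–Whitney statistic: the mean over test
samples of the fraction of candidates scored strictly lower plus half
the fraction tied. The ROC is the exact staircase of per-test
candidate percentiles, so its trapezoidal area equals the rank-sum AUC
to machine precision (tested at 1e-9).

By default every fold refits the entire model — including the GIP
kernels — on the masked matrix. This is the conservative protocol:
interaction profiles are defined by known associations only, so
computing them once from the full matrix would leak each held-out pair
into its own fold's kernels. The `recompute_kernels=False` variant
(CLI `--no-recompute-kernels`) scores once from the full data and is
provided for comparison; on planted-block synthetic data it saturates
the AUC to ≈1.0 precisely because of that leakage, which is a useful
demonstration of why the conservative protocol is the default.

Repeated k-fold CV shuffles the known associations with seed
`master + r` for repeat `r`, partitions them into near-equal subsets
(sizes differ by ≤ 1), and reports the mean and *sample* standard
deviation of per-repeat AUCs (the "±" convention in this literature is
rarely defined; we document ours). With folds = number of known
associations the procedure reduces exactly to global LOOCV (tested).

Auxiliary analyses: Pearson correlations between all unordered
disease-profile pairs (zero-variance profiles recorded as missing
rather than zero), and a two-sided Wilcoxon rank-sum comparison of two
score groups (exact null distribution when small and tie-free,
tie-corrected normal approximation otherwise).

## Synthetic data

The generator plants shared latent blocks: miRNAs and diseases are
assigned round-robin to `n_blocks` blocks, a pair associates with
probability `p_in` within a block and `p_out` across, and the
similarity matrices are block-co-membership indicators plus symmetric
uniform noise (drawn on the upper triangle and mirrored), clipped to
[0, 1] with unit diagonal. Because the same blocks couple both axes,
similarity genuinely predicts association, so above-chance CV AUC is a
meaningful correctness signal. Defaults — 100 miRNAs × 40 diseases, 5
blocks, p_in = 0.3, p_out = 0.01, noise 0.1 — give ~270 known
associations, a density (~6.6%) and per-disease association count of
the same order as real curated databases, at a size where a full LOOCV
runs in about a second. Setting `p_in = p_out` produces structureless
data for null calibration (the AUC must sit near 0.5; the ranking is
leakage-free, so it does). The DAG generator builds tree-shaped
ancestor graphs over a vocabulary that is either shared between
diseases or private, controlling how many disease pairs have nonzero
semantic similarity.

What the synthetic data does **not** emulate: scale-free degree
distributions, the heavy skew of real per-disease association counts,
correlated noise between the two similarity sources, and ontology
depth structure in real MeSH DAGs. Passing the synthetic checks
demonstrates correctness of the machinery and calibration of the
evaluation, not the headline accuracy attainable on a real curated
database.

## Known limitations

- Under the leakage-free protocol, planted-block global LOOCV AUC
  lands around 0.81–0.86 across seeds. Two effects bound it: roughly
  12% of planted positives are background (`p_out`) pairs carrying no
  block signal — alone capping the expected AUC near 0.94 even for a
  perfect in-block ranker — and the identity additions in the
  diffusion recipe make the fused kernels diagonally dominant,
  limiting how much association mass spreads to held-out pairs.
- The fused-kernel construction is asymmetric in its views only
  through the ε lift; swapping views with matched preprocessing is an
  exact symmetry (tested), but users supplying a kernel as the
  "similarity" view will see the ε perturbation applied to it.
- Identifier matching is exact-string after trimming and lowercasing;
  reconciling disease-name variants across vocabularies is out of
  scope and must be done upstream.
- Scores are relative rankings, not calibrated probabilities; no
  per-disease normalization is applied.
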