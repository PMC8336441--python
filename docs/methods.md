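# Methods

This package implements an interpretable convolutional pipeline for
classifying long-term survival (LTS) from gene-level multi-omics data and
for identifying the pathways that drive the classification. This note
records the model, the choices made where the design was genuinely open,
and what the synthetic-data tests do and do not establish.

## Pathway images

Each omics matrix (samples × genes; typically mRNA expression `EXP`, copy
number `CNV`, DNA methylation `MET`) is reduced pathway by pathway. For
pathway *p* with member genes *r_p*, the block *B* ∈ R^{n×r_p} is
mean-centered per gene and decomposed by PCA; the first *q* score columns
represent the pathway in that omics type. Stacking all pathways (rows) and
all omics types × PCs (columns, omics-major) yields a per-sample image
K ∈ R^{P×Oq} — e.g. 146 × 6 for 146 pathways, three omics types and q = 2.

Choices:

- **Missing genes** are dropped from the block before PCA; no imputation.
  If a block has fewer than *q* usable components, trailing image columns
  are zero-padded so image geometry is fixed.
- **Sign convention.** PCA signs are arbitrary; we flip each component so
  its largest-magnitude loading is positive (ties resolved by the first
  gene in sorted gene-id order). This makes images bit-reproducible and
  invariant to gene column order.
- **Centering only** by default (covariance PCA); per-gene unit-variance
  scaling is available via a flag. Within one omics block units are
  homogeneous, so scaling is not forced.
- **Scaling into the network.** PC scores have heterogeneous scales across
  pathways, so each pixel position is min–max mapped to [0,1] using
  statistics from a reference sample set (the full labeled cohort in the
  default workflow); held-out samples are clipped into [0,1] and constant
  pixels map to 0.
- **PCA fitting cohort.** By default PCA is fitted once on the full labeled
  cohort, matching the workflow in which image construction precedes
  cross-validation. Refitting per training fold would be the statistically
  safer choice with respect to leakage; the building blocks
  (`pathway_pca`, `ImageNormalizer`) accept arbitrary reference samples so
  a within-fold variant can be assembled, but the default mirrors the
  canonical pipeline.

## Labels

LTS is survival beyond a threshold (default 2 years) regardless of event
status; non-LTS is death at or before the threshold. Samples censored at or
before the threshold carry no label and are excluded from all analysis.

## Row ordering

Convolutions act locally, so correlated pathways should be adjacent.
Pathway *i*'s feature vector is its image row concatenated over samples
(length n·O·q, raw pre-normalization values); the P × P Pearson matrix of
these vectors drives a greedy chain: the most correlated pair occupies rows
1–2 (lower input index first — the rule does not orient the pair), then row
*i* takes the unplaced pathway most correlated (signed, not absolute) with
row *i−1*. Ties break by input order. This is a greedy heuristic, not an
optimal seriation.

## Classifier

Fixed architecture: conv 3×3 ×32 + ReLU → conv 3×3 ×64 + ReLU → max-pool
4×2 → dropout 0.25 → flatten (optionally concatenated with z-scored age,
standardized with training-fold statistics) → dense 64 + ReLU → dropout
0.5 → softmax over {LTS, non-LTS}. Both conv layers use `same` padding by
default: with `valid` padding the pooled map is one column wide and the
up-sampled activation maps could not differ across PC columns. Max-pooling
uses non-overlapping windows with floor semantics (trailing rows that do
not fill a window are dropped), the Keras default — a 146 × 6 input pools
to 36 × 3 × 64.

Training: weighted cross-entropy with class weights w_c = N/(2 n_c)
(minority class up-weighted; for a 55/232 cohort the weight ratio is
232/55 ≈ 4.22), Adam at learning rate 1e-4, 30 epochs, batch size 64. When
a validation set is provided, the parameter snapshot with the best
validation AUC is kept ("tuning" is realized as epoch snapshotting only —
all other hyper-parameters are fixed); a single-class validation set
triggers a warning and the final epoch is used. The network is implemented
directly in NumPy with explicit forward and backward passes, which also
gives exact access to the gradients Grad-CAM needs.

Evaluation uses the repeated stratified 5-fold protocol (default 30
repeats): per repeat a stratified partition into 5 test folds; per fold the
remaining samples are split 80/20 (stratified) into training/validation; a
fresh network is trained per fold; test AUC is recorded. Stratification is
used because with a ~1:4 imbalance unstratified folds can lack a class.
All fold assignments and weight initialisations derive from a master seed
via named substreams, so a rerun reproduces every split AUC exactly.

## Grad-CAM interpretation

For class c with pre-softmax logit y^c and last-conv (post-ReLU) feature
maps A^k (h × w):

    w_k^c = (1/Z) Σ_ij ∂y^c/∂A^k_ij,   Z = h·w
    L^c   = ReLU(Σ_k w_k^c A^k)

The logit (not the softmax probability) is differentiated — probability
gradients saturate; a flag restores the probability variant. L^c is min–max
normalized to [0,1] per (sample, class) *before* up-sampling (order
unspecified in general; normalizing first makes the difference maps
scale-free), then bilinearly up-sampled with corner alignment to the input
image size (nearest-neighbour available).

The interpretation model is trained once on **all** labeled samples with a
fixed seed and **without** the age input, so the maps reflect omics signal
independent of age. Each sample yields D_i = |L_i^LTS − L_i^non-LTS|; for
each pixel, D values are compared between the two groups with a two-sided
Wilcoxon rank-sum test — exact enumeration when the smaller group has ≤ 10
samples and there are no ties, otherwise the normal approximation with tie
and continuity corrections; pixels identical in both groups get p = 1 —
and Bonferroni-corrected over all P·Oq pixels. Pixels below the adjusted
threshold (default α = 0.001, a CLI parameter) are grouped into hot spots
by 4-connectivity (single-pixel components included). As a classical
follow-up, each top pixel's raw PC values are median-split (low: value ≤
median) and the two groups compared by Kaplan–Meier curves and a log-rank
test (via lifelines).

## Synthetic cohorts

The generator emulates the structure the pipeline assumes, not any real
tumour cohort. Gene value for sample s, gene g of pathway p, omics o:

    x = δ·1[s ∈ LTS]·1[(p,o) planted] + √ρ·F_{s,p,o} + √(1−ρ)·ε

with F, ε standard normal — marginal variance 1, so the planted shift δ is
in gene-SD units, and genes within a pathway correlate at ρ. Defaults
chosen once to mirror the emulated cohort's scale: n = 300 samples, 40
pathways × 20 genes, ρ = 0.3, δ = 1, 10% of genes missing per omics, LTS
fraction 0.2 (≈ 55/287), age 48 ± 8 y for LTS with the non-LTS group 13 y
older, 5% of samples censored before the 2-year threshold (exercising the
exclusion rule), 10% censoring among LTS. Survival times respect the label
threshold by construction (truncated/shifted exponentials), so label
recovery is interpretable; an optional label-noise fraction (default 0)
and a cross-pathway factor-mixing weight (default 0) are available.

Not emulated: realistic CNV segmentation, beta-distributed methylation,
batch effects, overlapping gene sets, or realistic hazard shapes. Passing
tests therefore establish that the pipeline recovers pathway-level mean
shifts embedded in correlated Gaussian blocks — not performance on real
tumour data.

## Verification problem sizes

The test suite and `scripts/acceptance.py` run entirely on synthetic data:
image geometry on a 146-pathway cohort (n = 60); Grad-CAM gradients against
a central finite-difference oracle (50 random inputs, relative 1e-3, on a
reduced-width network); ordering against a brute-force trace on 200 random
6–8-pathway matrices; planted-signal recovery on 10 cohorts (n = 300, 40
pathways, 4 planted pathways at δ = 2); null calibration at δ = 0 (CV with
2 repeats × 5 folds; 20 label permutations of the pixel tests); protocol
invariants at n = 100 with shortened training (5 epochs — the invariants
concern splits and determinism, not fit quality).

## Numerical notes

- All network arithmetic is float32; gradient checks cast to float64.
- Determinism holds for a fixed BLAS/thread configuration; all RNG streams
  are `numpy.random.Generator`s derived from named `SeedSequence`
  substreams so stage insertion does not shift other stages' draws.
- Zero-variance pathway blocks produce all-zero scores (explained-variance
  ratios defined as 0); zero-variance feature vectors correlate 0 with
  everything in the ordering step.

## Known limitations

- Greedy ordering is order-1 seriation; hot spots spanning pathways that
  the greedy chain separates will be fragmented.
- Full-cohort PCA/normalization (the default, mirroring the canonical
  workflow) leaks marginal distribution information into CV folds; the
  measured CV AUC is accordingly an optimistic estimate. The null
  calibration check bounds the size of this effect at δ = 0.
- The Grad-CAM difference-map statistic detects pathways the *model* uses;
  with collinear planted signals it may rank a correlated non-planted
  pathway highly (the ordering step makes this more, not less, likely by
  design).
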