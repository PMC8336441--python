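# pathcnn

Interpretable CNN classification of long-term cancer survival from
multi-omics data, with Grad-CAM-based discovery of survival-associated
pathways.

Gene-level omics matrices (e.g. mRNA expression, copy number, DNA
methylation) are not grid-structured, so convolutional networks cannot
consume them directly. This package converts them into per-sample
**pathway images**: for every pathway *p* and omics type, the member-gene
block B ∈ R^{n×r_p} is reduced by PCA to its first *q* score columns, and
the scores are stacked into a P × (O·q) image per sample (rows =
pathways, columns = omics-major PCs; 146 × 6 for 146 pathways, 3 omics
types, q = 2). Rows are ordered so that correlated pathways are adjacent
(greedy most-correlated-neighbour chaining), pixels are min–max scaled to
[0,1], and a small CNN — conv 3×3×32, conv 3×3×64, max-pool 4×2, dense 64,
softmax, optionally fed a z-scored age covariate — classifies long-term
survivors (LTS, survival > 2 years) against non-LTS, with class weights
w_c = N/(2 n_c) for the ~1:4 imbalance and repeated stratified 5-fold
cross-validation measuring AUC.

Interpretation uses Grad-CAM: for class c with logit y^c and last-conv
feature maps A^k,

    w_k^c = (1/Z) Σ_ij ∂y^c/∂A^k_ij ,    L^c = ReLU(Σ_k w_k^c A^k),

normalized to [0,1] and up-sampled to image size. Per sample,
D_i = |L_i^LTS − L_i^non-LTS|; each pixel's D values are compared between
the two survival groups with a two-sided Wilcoxon rank-sum test,
Bonferroni-corrected over all pixels. Contiguous significant pixels form
**hot spots** of survival-associated pathways, followed up with
Kaplan–Meier median-split log-rank tests on the underlying PC values.

The CNN (forward, backward, Adam, and the exact feature-map gradients
Grad-CAM needs) is implemented directly in NumPy; PCA, rank tests, fold
stratification, AUC, and survival analysis go through scikit-learn, SciPy
and lifelines. A synthetic-cohort generator with planted pathway-level
signal makes every stage testable without external data.

## Worked example

```python
import sys; sys.path.insert(0, "tests")   # for the build_cohort_images helper
from pathcnn import SyntheticConfig, PathCNNClassifier, ModelConfig
from conftest import build_cohort_images

# synthetic cohort: 200 samples, 20 pathways, 2 planted signal pathways
cfg = SyntheticConfig(n_samples=200, n_pathways=20, effect_size=2.0,
                      signal_pathways=((0, "EXP"), (1, "EXP")), seed=7)
normalized, raw, labels, clinical = build_cohort_images(cfg, q=2)

clf = PathCNNClassifier(normalized, labels, config=ModelConfig(use_age=False))
cv = clf.fit_cv(n_repeats=2, n_folds=5, seed=0)
print(cv.summary())

results = clf.fit(seed=0)                 # full-cohort model for Grad-CAM
print(results.interpret(alpha=0.001).summary())
```

prints

```
Repeated stratified cross-validation
  repeats x folds : 2 x 5
  AUC             : 0.755 +/- 0.075
  per-repeat means: 0.734 0.776

Grad-CAM pathway interpretation
  pixels tested   : 120
  alpha (adjusted): 0.001
  significant px  : 3
  hot spots       : 2 (sizes [1, 2])
  unique pathways : ['PATHWAY_000', 'PATHWAY_001', 'PATHWAY_003']
```

The cross-validated AUC of 0.755 ± 0.075 says the classifier separates the
two survival groups well above chance on held-out folds; the
interpretation stage flags 3 of the 120 image pixels as significant after
Bonferroni correction, and the hot spots contain both planted signal
pathways (`PATHWAY_000`, `PATHWAY_001`) plus one correlated neighbour.

The same workflow is available from the shell:

```bash
pathcnn simulate --out cohort/ --n-samples 200 --effect-size 2.0 --seed 7
pathcnn run --config demo.yaml          # images -> order -> CV -> interpret
pathcnn interpret --images out/images.npz --clinical cohort/clinical.tsv \
    --alpha 0.001 --out out/interpret/
```

`pathcnn run` writes every artefact (images NPZ, pathway order, per-split
AUCs, p-value matrices, hot-spot report, log-rank table) plus a
`manifest.json` with content hashes; a rerun with the same config and seed
reproduces the hashes exactly.

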