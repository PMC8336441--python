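"""Grad-CAM interpretation of the trained classifier and the downstream
pathway statistics.

For a class c with pre-softmax logit y^c and last-conv feature maps A^k
(h x w, K maps), the neuron importance weights are the spatially averaged
gradients

    w_k^c = (1/Z) * sum_ij  d y^c / d A^k_ij ,      Z = h * w,

and the class activation map is L^c = ReLU(sum_k w_k^c A^k), min-max
normalized to [0,1] and bilinearly up-sampled (corner-aligned) to the
input pathway-image size.  Each sample yields two maps (LTS and non-LTS);
their absolute difference D_i = |L_i^LTS - L_i^non-LTS| is compared
pixel-wise between the two survival groups with a two-sided Wilcoxon
rank-sum test, Bonferroni-corrected over all pixels.  Contiguous
significant pixels form "hot spots" of survival-associated pathways, and
a Kaplan-Meier median-split of the underlying PC values provides the
classical survival-analysis follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import mannwhitneyu

from .datatypes import LTS, NON_LTS, ClinicalTable, LabelSet, PathwayImageSet
from .nn import PathCNNNet

__all__ = [
    "GradCamResult",
    "DifferenceMapSet",
    "PixelTestResult",
    "HotSpot",
    "InterpretationResult",
    "gradcam_weights",
    "gradcam_map",
    "difference_maps",
    "pixelwise_test",
    "find_hotspots",
    "km_logrank_median_split",
    "interpret_model",
    "upsample",
]

_CLASS_IDX = {NON_LTS: 0, LTS: 1}


# --------------------------------------------------------------------------- #
# Grad-CAM


@dataclass
class GradCamResult:
    sample_id: str
    class_tag: str
    feature_maps: np.ndarray  # h x w x K
    neuron_weights: np.ndarray  # K
    raw_map: np.ndarray  # h x w, nonnegative
    upsampled_map: np.ndarray  # rows x cols in [0,1]


def _interp_axis0(a: np.ndarray, n_out: int, mode: str) -> np.ndarray:
    n_in = a.shape[0]
    if n_in == 1:
        return np.repeat(a, n_out, axis=0)
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    if mode == "nearest":
        return a[np.rint(pos).astype(int)]
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (pos - lo).reshape((-1,) + (1,) * (a.ndim - 1))
    return a[lo] * (1 - frac) + a[hi] * frac


def upsample(m: np.ndarray, out_shape: tuple[int, int], mode: str = "bilinear") -> np.ndarray:
    """Corner-aligned up-sampling of a 2-D map (bilinear or nearest)."""
    if mode not in ("bilinear", "nearest"):
        raise ValueError("mode must be 'bilinear' or 'nearest'")
    out = _interp_axis0(np.asarray(m, dtype=float), out_shape[0], mode)
    return _interp_axis0(out.T, out_shape[1], mode).T


def gradcam_weights(net: PathCNNNet, image: np.ndarray, class_tag: str,
                    age: Optional[float] = None) -> np.ndarray:
    """Neuron importance weights w_k^c: spatial mean of the class-logit
    gradient over each last-conv feature map."""
    if class_tag not in _CLASS_IDX:
        raise ValueError(f"unknown class {class_tag!r}; expected {LTS!r} or {NON_LTS!r}")
    x = np.asarray(image, dtype=float)[None, ...]
    a = None if age is None else np.asarray([age], dtype=float)
    _, da = net.conv_activations_and_grad(x, _CLASS_IDX[class_tag], age=a)
    return da[0].mean(axis=(0, 1)).astype(float)


def _normalize01(m: np.ndarray) -> np.ndarray:
    lo, hi = float(m.min()), float(m.max())
    if hi <= lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def gradcam_map(net: PathCNNNet, image: np.ndarray, class_tag: str,
                out_shape: Optional[tuple[int, int]] = None,
                interp: str = "bilinear", age: Optional[float] = None,
                sample_id: str = "") -> GradCamResult:
    """Full Grad-CAM map for one sample and class: ReLU-weighted feature-map
    sum, normalized to [0,1], then up-sampled to the input image shape."""
    if class_tag not in _CLASS_IDX:
        raise ValueError(f"unknown class {class_tag!r}")
    x = np.asarray(image, dtype=float)[None, ...]
    a = None if age is None else np.asarray([age], dtype=float)
    acts, da = net.conv_activations_and_grad(x, _CLASS_IDX[class_tag], age=a)
    A = acts[0].astype(float)  # h x w x K
    w = da[0].mean(axis=(0, 1)).astype(float)  # K
    raw = np.maximum((A * w[None, None, :]).sum(axis=2), 0.0)
    out_shape = out_shape or net.image_shape
    up = np.clip(upsample(_normalize01(raw), out_shape, mode=interp), 0.0, 1.0)
    return GradCamResult(
        sample_id=sample_id, class_tag=class_tag, feature_maps=A,
        neuron_weights=w, raw_map=raw, upsampled_map=up,
    )


# --------------------------------------------------------------------------- #
# Difference maps and pixel statistics


@dataclass
class DifferenceMapSet:
    sample_ids: list[str]
    maps: np.ndarray  # n x rows x cols, each |L^LTS - L^non-LTS| in [0,1]
    group: list[str]  # original class per sample

    @property
    def lts_mask(self) -> np.ndarray:
        return np.asarray([g == LTS for g in self.group], dtype=bool)


def difference_maps(net: PathCNNNet, images: PathwayImageSet, labels: LabelSet,
                    interp: str = "bilinear") -> DifferenceMapSet:
    """Per-sample absolute difference between the two class activation maps.

    The interpretation model is trained without the age covariate so the
    maps reflect the omics signal alone.
    """
    if net.use_age:
        raise ValueError("interpretation model must be trained without the age input")
    if list(images.sample_ids) != list(labels.sample_ids):
        raise ValueError("image and label sample ids are not aligned")
    n = len(images.sample_ids)
    maps = np.zeros((n,) + images.images.shape[1:3])
    for i, sid in enumerate(images.sample_ids):
        m_lts = gradcam_map(net, images.images[i], LTS, interp=interp, sample_id=sid)
        m_non = gradcam_map(net, images.images[i], NON_LTS, interp=interp, sample_id=sid)
        maps[i] = np.abs(m_lts.upsampled_map - m_non.upsampled_map)
    return DifferenceMapSet(sample_ids=list(images.sample_ids), maps=maps, group=list(labels.labels))


@dataclass
class PixelTestResult:
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    n_tests: int
    alpha: float
    row_labels: list[str] = field(default_factory=list)
    col_labels: list = field(default_factory=list)

    @property
    def significant_mask(self) -> np.ndarray:
        return self.adjusted_p < self.alpha

    def mask_at(self, alpha: float) -> np.ndarray:
        return self.adjusted_p < alpha


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value: exact enumeration when the
    smaller group has <= 10 samples and there are no ties, otherwise the
    normal approximation with tie and continuity corrections.  Degenerate
    pixels (all values identical) return p = 1 by convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    both = np.concatenate([x, y])
    if np.all(both == both[0]):
        return 1.0
    no_ties = len(np.unique(both)) == len(both)
    method = "exact" if (min(len(x), len(y)) <= 10 and no_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def pixelwise_test(diffs: DifferenceMapSet, alpha: float = 0.001,
                   row_labels: Optional[Sequence[str]] = None,
                   col_labels: Optional[Sequence] = None) -> PixelTestResult:
    """Per-pixel rank-sum test of difference-map values between the two
    survival groups, Bonferroni-corrected over all rows x cols pixels."""
    lts = diffs.lts_mask
    if lts.sum() < 2 or (~lts).sum() < 2:
        raise ValueError("both groups need at least 2 samples for the pixel tests")
    n, rows, cols = diffs.maps.shape
    raw = np.ones((rows, cols))
    for j in range(rows):
        for k in range(cols):
            raw[j, k] = rank_sum_p(diffs.maps[lts, j, k], diffs.maps[~lts, j, k])
    n_tests = rows * cols
    adjusted = np.minimum(1.0, raw * n_tests)
    return PixelTestResult(
        raw_p=raw, adjusted_p=adjusted, n_tests=n_tests, alpha=alpha,
        row_labels=list(row_labels or []), col_labels=list(col_labels or []),
    )


@dataclass
class HotSpot:
    pixels: list[tuple[int, int]]
    pathways: list[str]
    columns: list

    @property
    def size(self) -> int:
        return len(self.pixels)


def find_hotspots(result: PixelTestResult, alpha: Optional[float] = None) -> list[HotSpot]:
    """4-connected components of the significant-pixel mask, with pathway
    and (omics, PC) labels attached when available."""
    mask = result.mask_at(alpha if alpha is not None else result.alpha)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labeled, n_comp = ndimage.label(mask, structure=structure)
    spots = []
    for c in range(1, n_comp + 1):
        pix = [(int(r), int(k)) for r, k in np.argwhere(labeled == c)]
        pathways = sorted({result.row_labels[r] for r, _ in pix}) if result.row_labels else []
        columns = sorted({result.col_labels[k] for _, k in pix}) if result.col_labels else []
        spots.append(HotSpot(pixels=pix, pathways=pathways, columns=columns))
    return spots


def unique_hotspot_pathways(spots: Sequence[HotSpot]) -> list[str]:
    return sorted({p for s in spots for p in s.pathways})


# --------------------------------------------------------------------------- #
# Kaplan-Meier follow-up


@dataclass
class KMResult:
    statistic: float
    p_value: float
    km_low: "object"  # lifelines KaplanMeierFitter for the low group
    km_high: "object"
    n_low: int
    n_high: int


def km_logrank_median_split(pixel_values: np.ndarray, clinical: ClinicalTable) -> KMResult:
    """Dichotomize samples at the median of a per-sample value (e.g. a PC
    score) and compare survival between the halves with a log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    v = np.asarray(pixel_values, dtype=float)
    if len(v) != len(clinical.sample_id):
        raise ValueError("pixel values and clinical table have different lengths")
    med = float(np.median(v))
    low = v <= med
    if low.sum() < 2 or (~low).sum() < 2:
        raise ValueError("degenerate median split (need >= 2 samples on each side)")
    t, e = clinical.survival_years, clinical.event
    res = logrank_test(t[low], t[~low], event_observed_A=e[low], event_observed_B=e[~low])
    km_low, km_high = KaplanMeierFitter(), KaplanMeierFitter()
    km_low.fit(t[low], e[low], label="low")
    km_high.fit(t[~low], e[~low], label="high")
    return KMResult(
        statistic=float(res.test_statistic), p_value=float(res.p_value),
        km_low=km_low, km_high=km_high, n_low=int(low.sum()), n_high=int((~low).sum()),
    )


# --------------------------------------------------------------------------- #
# One-call interpretation


@dataclass
class InterpretationResult:
    diffs: DifferenceMapSet
    pixel_test: PixelTestResult
    hotspots: list[HotSpot]

    def pathway_min_adjusted_p(self) -> dict:
        """Smallest adjusted p per pathway row (across its pixel columns)."""
        rows = self.pixel_test.row_labels
        mins = self.pixel_test.adjusted_p.min(axis=1)
        return {name: float(p) for name, p in zip(rows, mins)}

    def top_pathways(self, k: int = 10) -> list[str]:
        ranked = sorted(self.pathway_min_adjusted_p().items(), key=lambda kv: kv[1])
        return [name for name, _ in ranked[:k]]

    def summary(self) -> str:
        lines = [
            "Grad-CAM pathway interpretation",
            f"  pixels tested   : {self.pixel_test.n_tests}",
            f"  alpha (adjusted): {self.pixel_test.alpha}",
            f"  significant px  : {int(self.pixel_test.significant_mask.sum())}",
            f"  hot spots       : {len(self.hotspots)} "
            f"(sizes {[s.size for s in self.hotspots]})",
            f"  unique pathways : {unique_hotspot_pathways(self.hotspots)}",
        ]
        return "\n".join(lines)


def interpret_model(net: PathCNNNet, images: PathwayImageSet, labels: LabelSet,
                    alpha: float = 0.001, interp: str = "bilinear") -> InterpretationResult:
    diffs = difference_maps(net, images, labels, interp=interp)
    ptest = pixelwise_test(diffs, alpha=alpha, row_labels=images.row_labels,
                           col_labels=images.col_labels)
    return InterpretationResult(diffs=diffs, pixel_test=ptest, hotspots=find_hotspots(ptest))


# --------------------------------------------------------------------------- #
# Plot helpers (optional artefacts; matplotlib Agg-safe)


def plot_pvalue_heatmap(result: PixelTestResult, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, max(3, len(result.row_labels) * 0.06 + 1)))
    img = -np.log10(np.clip(result.adjusted_p, 1e-12, 1.0))
    im = ax.imshow(img, aspect="auto", cmap="Reds")
    ax.set_xlabel("image column (omics, PC)")
    ax.set_ylabel("pathway row")
    if result.col_labels:
        ax.set_xticks(range(len(result.col_labels)))
        ax.set_xticklabels([f"{o}:{j}" for o, j in result.col_labels], rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_km(res: KMResult, path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    res.km_low.plot_survival_function(ax=ax)
    res.km_high.plot_survival_function(ax=ax)
    ax.set_xlabel("years")
    ax.set_ylabel("survival probability")
    ax.set_title(title or f"log-rank p = {res.p_value:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
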