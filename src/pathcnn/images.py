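"""Pathway-image construction from gene-level multi-omics data.

Each omics matrix (samples x genes) is reduced pathway by pathway: the
columns belonging to a pathway's member genes form a block B (n x r_i),
which PCA decomposes into q orthogonal score columns.  Stacking the first
q PC scores of every pathway and omics type gives each sample a 2-D
"pathway image" of P rows (pathways) and O*q columns (omics-major), the
input of the convolutional classifier.

Missing genes are simply dropped from a block before PCA (no imputation).
PCA signs are fixed deterministically — the loading of largest magnitude
is made positive, ties resolved by the first gene in sorted gene-id order
— so images are reproducible bit-for-bit and invariant to gene column
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import (
    LTS,
    NON_LTS,
    ClinicalTable,
    GeneSetCollection,
    LabelSet,
    OmicsMatrix,
    PathwayImageSet,
    PCScores,
)

__all__ = [
    "read_gene_sets",
    "read_omics_matrix",
    "assign_labels",
    "pathway_pca",
    "compute_all_pc_scores",
    "assemble_images",
    "normalize_images",
    "ImageNormalizer",
]


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file: one gene set per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are collapsed; duplicate set names and
    lines with fewer than 3 fields are errors.
    """
    pathways: list[tuple[str, frozenset]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno} (<3 tab-separated fields)")
            name = fields[0]
            if name in seen:
                raise ValueError(f"{path}: duplicate pathway name {name!r} at line {lineno}")
            seen.add(name)
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}: pathway {name!r} at line {lineno} has no genes")
            pathways.append((name, genes))
    return GeneSetCollection(pathways)


def read_omics_matrix(path, omics_tag: str, genes_in_rows: bool = False) -> OmicsMatrix:
    """Read a TSV omics matrix (first column sample ids, remaining columns
    genes; ``genes_in_rows=True`` transposes on read).  Parsing is strict:
    any non-numeric body cell is an error naming its row and column."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header.strip():
        raise ValueError(f"{path}: empty omics file")
    head_cols = header.split("\t")[1:]
    if not genes_in_rows and len(set(head_cols)) != len(head_cols):
        dup = sorted({c for c in head_cols if head_cols.count(c) > 1})
        raise ValueError(f"{path}: duplicate gene column(s) {dup}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty omics file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: omics file has no data rows")
    if genes_in_rows:
        df = df.T
        cols = list(df.columns)
        if len(set(cols)) != len(cols):
            dup = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"{path}: duplicate gene column(s) {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at sample {df.index[r]!r}, gene {df.columns[c]!r}"
        )
    return OmicsMatrix(
        omics_tag=omics_tag,
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        values=numeric.to_numpy(dtype=float),
    )


def assign_labels(clinical: ClinicalTable, threshold_years: float = 2.0) -> LabelSet:
    """Split samples into long-term survivors (survival > threshold,
    regardless of event status) and non-long-term survivors (death within
    the threshold).  Samples censored at or before the threshold carry no
    label and are excluded."""
    if threshold_years <= 0:
        raise ValueError("threshold_years must be positive")
    ids, labels, excluded = [], [], []
    for sid, t, e in zip(clinical.sample_id, clinical.survival_years, clinical.event):
        if t > threshold_years:
            ids.append(sid)
            labels.append(LTS)
        elif e == 1:
            ids.append(sid)
            labels.append(NON_LTS)
        else:
            excluded.append(sid)
    return LabelSet(sample_ids=ids, labels=labels, excluded_ids=excluded)


def pathway_pca(omics: OmicsMatrix, genes, q: int, pathway_name: str = "",
                scale: bool = False) -> PCScores:
    """PCA of one pathway's gene block in one omics type.

    The gene set is intersected with the matrix's gene universe (missing
    genes dropped), columns are mean-centered (and optionally scaled to
    unit variance), and the first q PC scores are returned.  If fewer than
    q components exist, trailing columns are zero with explained variance
    ratio 0, preserving a fixed image geometry.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    universe = {g: i for i, g in enumerate(omics.gene_ids)}
    present = sorted(set(genes) & set(universe))
    if not present:
        raise ValueError(
            f"pathway {pathway_name or '<unnamed>'} has no genes present in omics {omics.omics_tag!r}"
        )
    B = omics.values[:, [universe[g] for g in present]].astype(float)
    n, g = B.shape
    Bc = B - B.mean(axis=0)
    if scale:
        sd = Bc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Bc = Bc / sd
    k = min(q, g, n)
    pca = PCA(n_components=k, svd_solver="full")
    with warnings.catch_warnings():
        # zero total variance -> sklearn divides by 0; the nan ratio is mapped to 0 below
        warnings.simplefilter("ignore", RuntimeWarning)
        scores_k = pca.fit_transform(Bc)
    load = pca.components_  # k x g
    # deterministic sign: largest-|loading| gene positive (ties -> first in
    # sorted gene-id order, which is the column order of B)
    for j in range(k):
        i_star = int(np.argmax(np.abs(load[j])))
        if load[j, i_star] < 0:
            scores_k[:, j] *= -1.0
            load[j] *= -1.0
    evr = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
    scores = np.zeros((n, q))
    scores[:, :k] = scores_k
    evr_full = np.zeros(q)
    evr_full[:k] = evr
    return PCScores(
        pathway_name=pathway_name,
        omics_tag=omics.omics_tag,
        sample_ids=list(omics.sample_ids),
        scores=scores,
        explained_variance_ratio=evr_full,
        n_genes_used=g,
        n_genes_missing=len(set(genes)) - g,
    )


def compute_all_pc_scores(
    omics_list: Sequence[OmicsMatrix], gene_sets: GeneSetCollection, q: int, scale: bool = False
) -> dict:
    """All (pathway, omics) PC-score blocks, keyed by (pathway_name, omics_tag)."""
    return {
        (name, om.omics_tag): pathway_pca(om, genes, q, pathway_name=name, scale=scale)
        for name, genes in gene_sets
        for om in omics_list
    }


def assemble_images(
    pcs: Mapping[tuple[str, str], PCScores],
    order: Sequence[str],
    omics_tags: Sequence[str],
    q: int,
) -> PathwayImageSet:
    """Stack PC-score blocks into per-sample images.

    Row i of every image is pathway ``order[i]``; columns are omics-major:
    all q PCs of the first omics type, then the second, etc.
    """
    order = list(order)
    ref_key = (order[0], omics_tags[0])
    if ref_key not in pcs:
        raise ValueError(f"missing PC scores for {ref_key}")
    sample_ids = list(pcs[ref_key].sample_ids)
    n, p, o = len(sample_ids), len(order), len(omics_tags)
    images = np.zeros((n, p, o * q))
    for i, name in enumerate(order):
        for oi, tag in enumerate(omics_tags):
            key = (name, tag)
            if key not in pcs:
                raise ValueError(f"missing PC scores for pathway {name!r}, omics {tag!r}")
            block = pcs[key]
            if list(block.sample_ids) != sample_ids:
                raise ValueError(
                    f"sample sets differ across omics blocks: {key} vs {ref_key}"
                )
            images[:, i, oi * q : (oi + 1) * q] = block.scores[:, :q]
    col_labels = [(tag, j + 1) for tag in omics_tags for j in range(q)]
    return PathwayImageSet(images=images, row_labels=order, col_labels=col_labels, sample_ids=sample_ids)


@dataclass
class ImageNormalizer:
    """Per-pixel min-max parameters learned on reference samples; maps any
    image set to [0,1] with clipping (constant pixels map to 0)."""

    pixel_min: np.ndarray  # P x C
    pixel_max: np.ndarray  # P x C

    def transform(self, images: PathwayImageSet) -> PathwayImageSet:
        scale = self.pixel_max - self.pixel_min
        out = np.zeros_like(images.images)
        ok = scale > 0
        out[:, ok] = (images.images[:, ok] - self.pixel_min[ok]) / scale[ok]
        np.clip(out, 0.0, 1.0, out=out)
        return PathwayImageSet(
            images=out,
            row_labels=list(images.row_labels),
            col_labels=list(images.col_labels),
            sample_ids=list(images.sample_ids),
        )


def normalize_images(
    images: PathwayImageSet, reference_sample_ids: Optional[Sequence[str]] = None
) -> tuple[PathwayImageSet, ImageNormalizer]:
    """Min-max normalize every pixel position to [0,1].

    The min/max are computed on the reference samples only (default: all
    samples) so the same mapping can be reused on held-out data, where
    values are clipped into [0,1].
    """
    if reference_sample_ids is None:
        reference_sample_ids = images.sample_ids
    reference_sample_ids = list(reference_sample_ids)
    if not reference_sample_ids:
        raise ValueError("empty reference sample set")
    pos = {s: i for i, s in enumerate(images.sample_ids)}
    missing = [s for s in reference_sample_ids if s not in pos]
    if missing:
        raise ValueError(f"reference ids not in image set: {missing[:5]}")
    ref = images.images[[pos[s] for s in reference_sample_ids]]
    norm = ImageNormalizer(pixel_min=ref.min(axis=0), pixel_max=ref.max(axis=0))
    return norm.transform(images), norm
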