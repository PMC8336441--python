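"""Greedy correlation-based ordering of pathway rows.

Convolutional filters act locally, so pathways whose PC profiles are
correlated should sit on adjacent image rows.  Each pathway is described
by the concatenation over samples of its image row (length n*O*q); the
P x P Pearson correlation matrix of these vectors drives a greedy chain:
the most correlated pair occupies the top two rows, then each next row is
the not-yet-placed pathway most correlated with the previous row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import PathwayImageSet

__all__ = [
    "PathwayCorrelation",
    "pathway_correlation_matrix",
    "greedy_order",
    "apply_order",
    "save_order",
    "load_order",
]


@dataclass
class PathwayCorrelation:
    pathway_names: list[str]
    matrix: np.ndarray  # P x P, symmetric, unit diagonal

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        p = len(self.pathway_names)
        if self.matrix.shape != (p, p):
            raise ValueError("correlation matrix shape does not match pathway names")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("correlation matrix not symmetric")


def pathway_correlation_matrix(images: PathwayImageSet) -> PathwayCorrelation:
    """Pearson correlation between pathway feature vectors (image rows
    concatenated across samples).  Zero-variance vectors correlate 0 with
    everything off-diagonal."""
    n, p, c = images.shape
    if p < 2:
        raise ValueError("need at least 2 pathways to correlate")
    # vectors: P x (n*c)
    vec = images.images.transpose(1, 0, 2).reshape(p, n * c)
    centered = vec - vec.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered**2).sum(axis=1))
    corr = np.zeros((p, p))
    ok = sd > 0
    if ok.any():
        z = centered[ok] / sd[ok, None]
        corr[np.ix_(ok, ok)] = z @ z.T
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return PathwayCorrelation(pathway_names=list(images.row_labels), matrix=corr)


def greedy_order(corr: PathwayCorrelation) -> list[str]:
    """Chain pathways by the greedy most-correlated-neighbour rule.

    The globally most correlated off-diagonal pair fills rows 1-2 (the
    lower-input-index pathway first); row i then takes the unselected
    pathway with the highest correlation to the pathway in row i-1.  Ties
    are broken by input order throughout.
    """
    m = corr.matrix
    p = len(corr.pathway_names)
    if p < 2:
        raise ValueError("need at least 2 pathways to order")
    # best pair: lexicographically first (i, j) among maxima, i < j
    best, best_pair = -np.inf, (0, 1)
    for i in range(p):
        for j in range(i + 1, p):
            if m[i, j] > best:
                best, best_pair = m[i, j], (i, j)
    order_idx = [best_pair[0], best_pair[1]]
    remaining = [k for k in range(p) if k not in order_idx]
    while remaining:
        prev = order_idx[-1]
        # argmax over remaining with input-order tie-break
        nxt = max(remaining, key=lambda k: (m[prev, k], -k))
        order_idx.append(nxt)
        remaining.remove(nxt)
    return [corr.pathway_names[i] for i in order_idx]


def apply_order(images: PathwayImageSet, order: Sequence[str]) -> PathwayImageSet:
    """Permute image rows (and row labels) into the given pathway order."""
    order = list(order)
    if sorted(order) != sorted(images.row_labels):
        raise ValueError("order is not a permutation of the image row labels")
    pos = {name: i for i, name in enumerate(images.row_labels)}
    idx = [pos[name] for name in order]
    return PathwayImageSet(
        images=images.images[:, idx, :],
        row_labels=order,
        col_labels=list(images.col_labels),
        sample_ids=list(images.sample_ids),
    )


def save_order(order: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for name in order:
            fh.write(name + "\n")


def load_order(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
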