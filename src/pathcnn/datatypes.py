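"""Core data containers shared across the pipeline.

These are deliberately thin: validated dataclasses over NumPy arrays and
pandas frames, with explicit provenance labels (sample ids, gene ids,
pathway names, (omics, PC) column labels) so every downstream artefact —
images, activation maps, p-value matrices — stays interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

LTS = "LTS"
NON_LTS = "non-LTS"


@dataclass
class OmicsMatrix:
    """A samples x genes numeric matrix for one omics type (e.g. EXP, CNV, MET)."""

    omics_tag: str
    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, r = self.values.shape
        if len(self.sample_ids) != n or len(self.gene_ids) != r:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"duplicate sample ids in {self.omics_tag} matrix")
        if len(set(self.gene_ids)) != r:
            raise ValueError(f"duplicate gene ids in {self.omics_tag} matrix")
        if n < 2:
            raise ValueError("an omics matrix needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return OmicsMatrix(self.omics_tag, list(sample_ids), list(self.gene_ids), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class GeneSetCollection:
    """Ordered, uniquely named pathways with member gene sets."""

    pathways: list[tuple[str, frozenset]]

    def __post_init__(self):
        names = [n for n, _ in self.pathways]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate pathway name(s): {dup}")
        for name, genes in self.pathways:
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.pathways]

    def genes(self, name: str) -> frozenset:
        for n, g in self.pathways:
            if n == name:
                return g
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)


@dataclass
class ClinicalTable:
    """Per-sample survival follow-up: time (years), event flag, and age."""

    sample_id: list[str]
    survival_years: np.ndarray
    event: np.ndarray
    age: np.ndarray

    def __post_init__(self):
        self.survival_years = np.asarray(self.survival_years, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.age = np.asarray(self.age, dtype=float)
        n = len(self.sample_id)
        if not (len(self.survival_years) == len(self.event) == len(self.age) == n):
            raise ValueError("clinical columns have unequal lengths")
        if len(set(self.sample_id)) != n:
            raise ValueError("duplicate sample ids in clinical table")
        if np.any(self.survival_years < 0):
            raise ValueError("negative survival time")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "survival_years": self.survival_years,
                "event": self.event,
                "age": self.age,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClinicalTable":
        return cls(
            sample_id=[str(s) for s in df["sample_id"]],
            survival_years=df["survival_years"].to_numpy(),
            event=df["event"].to_numpy(),
            age=df["age"].to_numpy(),
        )

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        pos = {s: i for i, s in enumerate(self.sample_id)}
        idx = [pos[s] for s in sample_ids]
        return ClinicalTable(
            [self.sample_id[i] for i in idx],
            self.survival_years[idx],
            self.event[idx],
            self.age[idx],
        )


@dataclass
class LabelSet:
    """Survival-class labels after applying the follow-up exclusion rule.

    Samples alive at last follow-up before the threshold carry no usable
    label and are listed in ``excluded_ids``.
    """

    sample_ids: list[str]
    labels: list[str]  # LTS / non-LTS, aligned with sample_ids
    excluded_ids: list[str]

    def __post_init__(self):
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("labels and sample ids have unequal lengths")
        bad = set(self.labels) - {LTS, NON_LTS}
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    @property
    def y(self) -> np.ndarray:
        """Integer encoding: 1 = LTS, 0 = non-LTS."""
        return np.asarray([1 if l == LTS else 0 for l in self.labels], dtype=int)

    def counts(self) -> dict:
        y = self.y
        return {LTS: int(y.sum()), NON_LTS: int((1 - y).sum())}


@dataclass
class PCScores:
    """Principal-component scores of one pathway's gene block in one omics type."""

    pathway_name: str
    omics_tag: str
    sample_ids: list[str]
    scores: np.ndarray  # n x q
    explained_variance_ratio: np.ndarray  # length q
    n_genes_used: int
    n_genes_missing: int


@dataclass
class PathwayImageSet:
    """Stack of per-sample pathway images: (n, P, O*q) with full labelling."""

    images: np.ndarray
    row_labels: list[str]  # pathway names, display order
    col_labels: list[tuple[str, int]]  # (omics_tag, pc_index), omics-major
    sample_ids: list[str]

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        n, p, c = self.images.shape
        if len(self.row_labels) != p or len(self.col_labels) != c or len(self.sample_ids) != n:
            raise ValueError("image labels do not match image dimensions")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.images.shape

    def save_npz(self, path) -> None:
        np.savez(
            path,
            images=self.images,
            row_labels=np.array(self.row_labels),
            col_labels=np.array([f"{o}:{j}" for o, j in self.col_labels]),
            sample_ids=np.array(self.sample_ids),
        )

    @classmethod
    def load_npz(cls, path) -> "PathwayImageSet":
        with np.load(path, allow_pickle=False) as z:
            cols = []
            for lab in z["col_labels"]:
                o, j = str(lab).rsplit(":", 1)
                cols.append((o, int(j)))
            return cls(
                images=z["images"],
                row_labels=[str(s) for s in z["row_labels"]],
                col_labels=cols,
                sample_ids=[str(s) for s in z["sample_ids"]],
            )
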