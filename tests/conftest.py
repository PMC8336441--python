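import numpy as np
import pytest

from pathcnn.datatypes import LTS, NON_LTS, LabelSet, PathwayImageSet
from pathcnn.images import assemble_images, assign_labels, compute_all_pc_scores, normalize_images
from pathcnn.ordering import apply_order, greedy_order, pathway_correlation_matrix
from pathcnn.synthetic import SyntheticConfig, generate_cohort


def build_cohort_images(config: SyntheticConfig, q: int = 2):
    """Full preprocessing chain: cohort -> labels -> PCA -> assemble ->
    greedy order -> min-max normalization.  Returns (normalized images,
    raw ordered images, labels, clinical-of-labeled)."""
    omics, gene_sets, clinical = generate_cohort(config)
    labels = assign_labels(clinical, threshold_years=config.threshold_years)
    keep = labels.sample_ids
    omics = [om.subset_samples(keep) for om in omics]
    pcs = compute_all_pc_scores(omics, gene_sets, q)
    raw = assemble_images(pcs, gene_sets.names, list(config.omics_types), q)
    order = greedy_order(pathway_correlation_matrix(raw))
    raw = apply_order(raw, order)
    normalized, _ = normalize_images(raw)
    return normalized, raw, labels, clinical.subset(keep)


@pytest.fixture(scope="session")
def signal_cohort():
    """Moderate cohort with strong planted signal, shared across tests."""
    cfg = SyntheticConfig(n_samples=200, n_pathways=20, effect_size=2.0,
                          signal_pathways=((0, "EXP"), (1, "EXP")), seed=11)
    return build_cohort_images(cfg)


@pytest.fixture
def toy_labelset():
    return LabelSet(
        sample_ids=[f"s{i}" for i in range(6)],
        labels=[LTS, LTS, NON_LTS, NON_LTS, NON_LTS, NON_LTS],
        excluded_ids=["s6"],
    )


def make_image_set(images: np.ndarray, tags=("EXP",), q=None):
    n, p, c = images.shape
    q = q if q is not None else c // len(tags)
    return PathwayImageSet(
        images=images,
        row_labels=[f"PW{i}" for i in range(p)],
        col_labels=[(t, j + 1) for t in tags for j in range(q)],
        sample_ids=[f"s{i}" for i in range(n)],
    )
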