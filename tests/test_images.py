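"""Pathway-image construction: GMT/TSV parsing, label assignment,
per-pathway PCA (with the deterministic sign rule), image assembly and
min-max normalization."""

import numpy as np
import pytest

from pathcnn.datatypes import LTS, NON_LTS, ClinicalTable, OmicsMatrix
from pathcnn.images import (
    assemble_images,
    assign_labels,
    normalize_images,
    pathway_pca,
    read_gene_sets,
    read_omics_matrix,
)
from conftest import make_image_set


# ---------------------------------------------------------------- GMT parsing

def test_gmt_parse_and_duplicate_collapse(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("PATH_A\tdesc\tG1\tG2\tG3\nPATH_B\tdesc\tG1\tG1\n")
    gs = read_gene_sets(p)
    assert gs.names == ["PATH_A", "PATH_B"]
    assert gs.genes("PATH_A") == frozenset({"G1", "G2", "G3"})
    assert gs.genes("PATH_B") == frozenset({"G1"})


@pytest.mark.parametrize("content,msg", [
    ("PATH_A\tdesc\n", "malformed"),
    ("PATH_A\td\tG1\nPATH_A\td\tG2\n", "duplicate"),
])
def test_gmt_errors(tmp_path, content, msg):
    p = tmp_path / "bad.gmt"
    p.write_text(content)
    with pytest.raises(ValueError, match=msg):
        read_gene_sets(p)


# ---------------------------------------------------------------- omics TSV

def test_read_omics_matrix(tmp_path):
    p = tmp_path / "om.tsv"
    p.write_text("sample_id\tG1\tG2\ns1\t1.0\t2\ns2\t3\t4\ns3\t5\t6\n")
    om = read_omics_matrix(p, "EXP")
    assert (om.n_samples, om.n_genes) == (3, 2)
    np.testing.assert_array_equal(om.values, [[1, 2], [3, 4], [5, 6]])


def test_read_omics_genes_in_rows(tmp_path):
    p = tmp_path / "om.tsv"
    p.write_text("gene\ts1\ts2\ts3\nG1\t1\t3\t5\nG2\t2\t4\t6\n")
    om = read_omics_matrix(p, "EXP", genes_in_rows=True)
    assert om.sample_ids == ["s1", "s2", "s3"]
    np.testing.assert_array_equal(om.values, [[1, 2], [3, 4], [5, 6]])


@pytest.mark.parametrize("content,msg", [
    ("sample_id\tG1\tG2\ns1\tNA\t2\ns2\t3\t4\n", "non-numeric"),
    ("sample_id\tG1\tG1\ns1\t1\t2\ns2\t3\t4\n", "duplicate gene"),
    ("sample_id\tG1\tG2\n", "no data rows"),
    ("", "empty"),
])
def test_read_omics_errors(tmp_path, content, msg):
    p = tmp_path / "bad.tsv"
    p.write_text(content)
    with pytest.raises(ValueError, match=msg):
        read_omics_matrix(p, "EXP")


# ---------------------------------------------------------------- labels

def test_assign_labels_threshold_rules():
    clinical = ClinicalTable(
        sample_id=["a", "b", "c", "d"],
        survival_years=[1.5, 1.5, 3.0, 2.0],
        event=[1, 0, 0, 1],
        age=[60, 60, 60, 60],
    )
    ls = assign_labels(clinical, 2.0)
    lab = dict(zip(ls.sample_ids, ls.labels))
    assert lab["a"] == NON_LTS          # death within threshold
    assert "b" not in lab               # censored early -> excluded
    assert ls.excluded_ids == ["b"]
    assert lab["c"] == LTS              # alive beyond threshold
    assert lab["d"] == NON_LTS          # death exactly at threshold


def test_assign_labels_rejects_bad_threshold():
    clinical = ClinicalTable(["a", "b"], [1.0, 2.0], [1, 1], [50, 50])
    with pytest.raises(ValueError):
        assign_labels(clinical, 0.0)


# ---------------------------------------------------------------- PCA

def _om(values, genes, tag="EXP"):
    n = len(values)
    return OmicsMatrix(tag, [f"s{i}" for i in range(n)], genes, np.asarray(values, float))


def test_pathway_pca_collinear_two_genes():
    # B has perfectly collinear columns: PC1 captures everything, scores
    # +-sqrt(5) by hand eigendecomposition of the 2x2 covariance.
    om = _om([[1, 2], [2, 4], [3, 6]], ["G1", "G2"])
    pcs = pathway_pca(om, {"G1", "G2"}, q=2, pathway_name="P")
    np.testing.assert_allclose(pcs.scores[:, 0], [-np.sqrt(5), 0, np.sqrt(5)], atol=1e-9)
    np.testing.assert_allclose(pcs.scores[:, 1], 0, atol=1e-9)
    np.testing.assert_allclose(pcs.explained_variance_ratio, [1.0, 0.0], atol=1e-12)


def test_pathway_pca_constant_matrix_gives_zero_scores():
    om = _om([[5, 5], [5, 5], [5, 5]], ["G1", "G2"])
    pcs = pathway_pca(om, {"G1", "G2"}, q=2)
    np.testing.assert_allclose(pcs.scores, 0, atol=1e-12)


def test_pathway_pca_gene_order_invariance():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=(15, 6))
    genes = [f"G{i}" for i in range(6)]
    om1 = _om(vals, genes)
    perm = rng.permutation(6)
    om2 = _om(vals[:, perm], [genes[i] for i in perm])
    p1 = pathway_pca(om1, set(genes), q=3)
    p2 = pathway_pca(om2, set(genes), q=3)
    np.testing.assert_allclose(p1.scores, p2.scores, atol=1e-9)


def test_pathway_pca_missing_genes_and_padding():
    rng = np.random.default_rng(1)
    om = _om(rng.normal(size=(10, 2)), ["G1", "G2"])
    pcs = pathway_pca(om, {"G1", "G2", "G3", "G4"}, q=4)
    assert pcs.n_genes_used == 2
    assert pcs.n_genes_missing == 2
    np.testing.assert_allclose(pcs.scores[:, 2:], 0)
    np.testing.assert_allclose(pcs.explained_variance_ratio[2:], 0)
    assert np.all(np.diff(pcs.explained_variance_ratio) <= 1e-12)


def test_pathway_pca_score_columns_orthogonal():
    rng = np.random.default_rng(2)
    om = _om(rng.normal(size=(30, 8)), [f"G{i}" for i in range(8)])
    pcs = pathway_pca(om, {f"G{i}" for i in range(8)}, q=4)
    gram = pcs.scores.T @ pcs.scores
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8 * np.abs(gram).max()


def test_pathway_pca_no_present_genes_errors():
    om = _om([[1, 2], [3, 4]], ["G1", "G2"])
    with pytest.raises(ValueError, match="no genes present"):
        pathway_pca(om, {"G9"}, q=1, pathway_name="P_X")


# ---------------------------------------------------------------- assembly

def _pcs_for(pathways, tags, n, q, seed=0):
    from pathcnn.datatypes import PCScores

    rng = np.random.default_rng(seed)
    out = {}
    for name in pathways:
        for tag in tags:
            out[(name, tag)] = PCScores(
                pathway_name=name, omics_tag=tag,
                sample_ids=[f"s{i}" for i in range(n)],
                scores=rng.normal(size=(n, q)),
                explained_variance_ratio=np.linspace(0.5, 0.1, q),
                n_genes_used=5, n_genes_missing=0,
            )
    return out


def test_assemble_geometry_146x6():
    paths = [f"PW{i}" for i in range(146)]
    pcs = _pcs_for(paths, ["EXP", "CNV", "MET"], n=4, q=2)
    imgs = assemble_images(pcs, paths, ["EXP", "CNV", "MET"], q=2)
    assert imgs.shape == (4, 146, 6)
    assert imgs.col_labels == [("EXP", 1), ("EXP", 2), ("CNV", 1), ("CNV", 2),
                               ("MET", 1), ("MET", 2)]


def test_assemble_degenerate_single_omics_q1():
    paths = ["PW0", "PW1", "PW2"]
    pcs = _pcs_for(paths, ["EXP"], n=5, q=1)
    imgs = assemble_images(pcs, paths, ["EXP"], q=1)
    assert imgs.shape == (5, 3, 1)


def test_assemble_reorder_permutes_rows_consistently():
    paths = ["PW0", "PW1", "PW2"]
    pcs = _pcs_for(paths, ["EXP"], n=5, q=2)
    a = assemble_images(pcs, paths, ["EXP"], q=2)
    b = assemble_images(pcs, ["PW2", "PW0", "PW1"], ["EXP"], q=2)
    assert b.row_labels == ["PW2", "PW0", "PW1"]
    np.testing.assert_array_equal(b.images[:, 0], a.images[:, 2])
    np.testing.assert_array_equal(b.images[:, 1], a.images[:, 0])


def test_assemble_missing_block_and_sample_mismatch_error():
    paths = ["PW0", "PW1"]
    pcs = _pcs_for(paths, ["EXP"], n=4, q=1)
    with pytest.raises(ValueError, match="missing PC scores"):
        assemble_images(pcs, paths, ["EXP", "CNV"], q=1)
    pcs[("PW1", "EXP")].sample_ids = [f"t{i}" for i in range(4)]
    with pytest.raises(ValueError, match="sample sets differ"):
        assemble_images(pcs, paths, ["EXP"], q=1)


# ---------------------------------------------------------------- scaling

def test_normalize_linear_map_clip_and_constant():
    vals = np.zeros((3, 2, 1))
    vals[:, 0, 0] = [-2.0, 2.0, 0.0]   # pixel A: min -2, max 2
    vals[:, 1, 0] = [7.0, 7.0, 7.0]    # pixel B: constant
    imgs = make_image_set(vals)
    normed, norm = normalize_images(imgs, reference_sample_ids=["s0", "s1"])
    assert normed.images[2, 0, 0] == pytest.approx(0.5)   # value 0 in [-2,2]
    np.testing.assert_allclose(normed.images[:, 1, 0], 0)  # constant -> 0
    # held-out value above the reference max clips to 1
    out = norm.transform(make_image_set(np.array([[[3.0], [7.0]]])))
    assert out.images[0, 0, 0] == 1.0


def test_normalize_empty_reference_errors(signal_cohort):
    normalized, raw, _, _ = signal_cohort
    with pytest.raises(ValueError):
        normalize_images(raw, reference_sample_ids=[])
    assert normalized.images.min() >= 0 and normalized.images.max() <= 1
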