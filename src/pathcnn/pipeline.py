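"""End-to-end orchestration: simulate -> images -> order -> CV -> interpret.

``run_pipeline`` composes the stages in their canonical order (label
assignment, per-pathway PCA, image assembly, correlation-based row
ordering, min-max normalization, repeated cross-validation, full-cohort
retraining without age, Grad-CAM interpretation) and writes every
artefact plus a manifest JSON with content hashes, so a rerun with the
same config and seed can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import images as img
from . import ordering
from .datatypes import ClinicalTable, PathwayImageSet
from .model import ModelConfig, PathCNNClassifier
from .interpret import km_logrank_median_split, plot_km, plot_pvalue_heatmap, unique_hotspot_pathways
from .synthetic import SyntheticConfig, generate_cohort, signal_pathway_names, write_cohort

logger = logging.getLogger("pathcnn")

__all__ = ["PipelineConfig", "run_pipeline", "simulate", "build_image_set"]


@dataclass
class PipelineConfig:
    omics: dict  # omics tag -> TSV path, insertion order = column order
    gene_sets: str
    clinical: str
    outdir: str
    q: int = 2
    threshold_years: float = 2.0
    genes_in_rows: bool = False
    pca_scale: bool = False
    use_age: bool = True
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-4
    padding_mode: str = "same"
    n_repeats: int = 30
    n_folds: int = 5
    alpha: float = 0.001
    km_top_pixels: int = 6
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.q < 1:
            raise ValueError("q must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def model_config(self, use_age: bool) -> ModelConfig:
        return ModelConfig(
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, padding_mode=self.padding_mode,
            use_age=use_age, seed=self.seed,
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_image_set(config: PipelineConfig):
    """Stages up to the normalized, ordered image stack.

    Returns (normalized images, raw ordered images, labels, clinical-of-labeled,
    pathway order).
    """
    gene_sets = img.read_gene_sets(config.gene_sets)
    omics_list = [
        img.read_omics_matrix(path, tag, genes_in_rows=config.genes_in_rows)
        for tag, path in config.omics.items()
    ]
    clinical = ClinicalTable.from_frame(pd.read_csv(config.clinical, sep="\t"))
    labels = img.assign_labels(clinical, threshold_years=config.threshold_years)
    # keep labeled samples present in every omics matrix, in clinical order
    common = set(labels.sample_ids)
    for om in omics_list:
        common &= set(om.sample_ids)
    keep = [s for s in labels.sample_ids if s in common]
    if len(keep) < len(labels.sample_ids):
        logger.warning("dropping %d labeled samples missing from some omics matrix",
                       len(labels.sample_ids) - len(keep))
    lab_pos = {s: i for i, s in enumerate(labels.sample_ids)}
    labels = type(labels)(
        sample_ids=keep,
        labels=[labels.labels[lab_pos[s]] for s in keep],
        excluded_ids=labels.excluded_ids,
    )
    omics_list = [om.subset_samples(keep) for om in omics_list]
    clinical_lab = clinical.subset(keep)

    pcs = img.compute_all_pc_scores(omics_list, gene_sets, config.q, scale=config.pca_scale)
    raw_images = img.assemble_images(pcs, gene_sets.names, list(config.omics.keys()), config.q)
    corr = ordering.pathway_correlation_matrix(raw_images)
    order = ordering.greedy_order(corr)
    raw_images = ordering.apply_order(raw_images, order)
    assert list(raw_images.sample_ids) == list(labels.sample_ids)
    normalized, _ = img.normalize_images(raw_images)
    return normalized, raw_images, labels, clinical_lab, order


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the artefact manifest (also written to
    ``outdir/manifest.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: seed=%d outdir=%s", config.seed, outdir)

    normalized, raw_images, labels, clinical_lab, order = build_image_set(config)
    logger.info("images: %s samples x %s pathways x %s columns", *normalized.shape)

    artifacts: dict[str, str] = {}
    images_path = outdir / "images.npz"
    normalized.save_npz(images_path)
    artifacts["images"] = str(images_path)
    order_path = outdir / "order.txt"
    ordering.save_order(order, order_path)
    artifacts["order"] = str(order_path)
    labels_path = outdir / "labels.tsv"
    with open(labels_path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for s, l in zip(labels.sample_ids, labels.labels):
            fh.write(f"{s}\t{l}\n")
        for s in labels.excluded_ids:
            fh.write(f"{s}\texcluded\n")
    artifacts["labels"] = str(labels_path)

    # cross-validated predictive performance (with age when configured)
    clf = PathCNNClassifier(
        normalized, labels,
        age=clinical_lab.age if config.use_age else None,
        config=config.model_config(use_age=config.use_age),
    )
    cv = clf.fit_cv(n_repeats=config.n_repeats, n_folds=config.n_folds, seed=config.seed)
    logger.info("cross-validation AUC %.3f +/- %.3f", cv.mean_auc, cv.sd_auc)
    cv_path = outdir / "cv.json"
    with open(cv_path, "w") as fh:
        json.dump({**cv.to_dict(), "config": asdict(config)}, fh, indent=2)
    artifacts["cv"] = str(cv_path)

    # full-cohort interpretation model: age removed
    clf_interp = PathCNNClassifier(normalized, labels, config=config.model_config(use_age=False))
    results = clf_interp.fit(seed=config.seed)
    model_path = outdir / "model.npz"
    results.net.save_npz(model_path)
    artifacts["model"] = str(model_path)
    interp = results.interpret(alpha=config.alpha)
    logger.info("interpretation: %d significant pixels, %d hot spots",
                int(interp.pixel_test.significant_mask.sum()), len(interp.hotspots))

    interp_dir = outdir / "interpret"
    interp_dir.mkdir(exist_ok=True)
    col_names = [f"{o}:PC{j}" for o, j in normalized.col_labels]
    for name, mat in (("raw_p", interp.pixel_test.raw_p), ("adjusted_p", interp.pixel_test.adjusted_p)):
        p = interp_dir / f"{name}.tsv"
        pd.DataFrame(mat, index=normalized.row_labels, columns=col_names).to_csv(p, sep="\t")
        artifacts[name] = str(p)
    hs_path = interp_dir / "hotspots.json"
    with open(hs_path, "w") as fh:
        json.dump(
            {
                "alpha": config.alpha,
                "hotspots": [
                    {"pixels": s.pixels, "pathways": s.pathways,
                     "columns": [list(c) for c in s.columns], "size": s.size}
                    for s in interp.hotspots
                ],
                "unique_pathways": unique_hotspot_pathways(interp.hotspots),
            },
            fh, indent=2,
        )
    artifacts["hotspots"] = str(hs_path)

    # Kaplan-Meier median-split follow-up on the most significant pixels,
    # using the raw (pre-normalization) PC values
    flat_order = np.argsort(interp.pixel_test.adjusted_p, axis=None)
    km_rows = []
    for flat in flat_order[: config.km_top_pixels]:
        r, k = np.unravel_index(flat, interp.pixel_test.adjusted_p.shape)
        values = raw_images.images[:, r, k]
        try:
            km = km_logrank_median_split(values, clinical_lab)
        except ValueError:
            continue
        o_tag, pc = normalized.col_labels[k]
        km_rows.append({
            "pathway": normalized.row_labels[r], "omics": o_tag, "pc": pc,
            "adjusted_p_pixel": float(interp.pixel_test.adjusted_p[r, k]),
            "logrank_statistic": km.statistic, "logrank_p": km.p_value,
            "n_low": km.n_low, "n_high": km.n_high,
        })
        if config.make_plots:
            plot_km(km, interp_dir / f"km_{normalized.row_labels[r]}_{o_tag}_PC{pc}.png",
                    title=f"{normalized.row_labels[r]} {o_tag} PC{pc}")
    km_path = interp_dir / "logrank.tsv"
    pd.DataFrame(km_rows).to_csv(km_path, sep="\t", index=False)
    artifacts["logrank"] = str(km_path)
    if config.make_plots:
        hm = interp_dir / "adjusted_p_heatmap.png"
        plot_pvalue_heatmap(interp.pixel_test, hm)
        artifacts["heatmap"] = str(hm)

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "artifacts": {name: {"path": p, "sha256": _sha256(p)} for name, p in artifacts.items()},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("manifest written: %s", manifest_path)
    return manifest


def simulate(config: SyntheticConfig, outdir) -> dict:
    """Generate a synthetic cohort and write it to disk alongside a
    ground-truth JSON naming the planted signal pathways."""
    omics_list, gene_sets, clinical = generate_cohort(config)
    truth = {
        "signal_pathways": signal_pathway_names(config),
        "signal_pairs": [[int(p), t] for p, t in config.signal_pathways],
        "effect_size": config.effect_size,
        "seed": config.seed,
    }
    return write_cohort(omics_list, gene_sets, clinical, outdir, truth=truth)
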