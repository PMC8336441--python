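"""Synthetic multi-omics cohorts with planted pathway-level survival signal.

The generator emulates the data layout the pipeline consumes: up to three
gene-level omics matrices over a shared sample cohort, KEGG-style gene
sets, and a clinical table (survival years, event flag, age).  Genes
within a pathway share a latent factor (correlation ``within_pathway_rho``),
and a chosen set of (pathway, omics) pairs carries a standardized mean
shift between long-term survivors (LTS) and non-LTS — the "signal"
downstream stages must recover.

Generative model for gene g of pathway p in omics o, sample s:

    x = effect_size * 1[s in LTS] * 1[(p,o) is signal]
        + sqrt(rho) * F[s,p,o] + sqrt(1-rho) * eps

with F and eps standard normal, so marginal gene variance is 1 and the
planted shift is expressed in gene-SD units.  Survival times respect the
2-year labelling threshold by construction (LTS > 2 y, non-LTS deaths
<= 2 y); a small fraction of samples is censored before the threshold to
exercise the label-exclusion rule, and LTS samples are censored at rate
``censor_rate`` (they remain LTS: survival beyond the threshold is
observed either way).  Age is overlapping-normal (SD 8 y) with the
non-LTS group older by ``age_shift`` years, mirroring the 48 vs 61 year
group means of the glioblastoma cohort this emulates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import ClinicalTable, GeneSetCollection, OmicsMatrix

__all__ = ["SyntheticConfig", "generate_cohort", "generate_fixture", "write_cohort", "signal_pathway_names"]

_FIXTURE_SEED = 20210712


@dataclass
class SyntheticConfig:
    n_samples: int = 300
    n_pathways: int = 40
    genes_per_pathway: int = 20
    omics_types: tuple = ("EXP", "CNV", "MET")
    signal_pathways: tuple = ((0, "EXP"), (1, "EXP"), (2, "EXP"), (3, "EXP"))
    effect_size: float = 1.0
    within_pathway_rho: float = 0.3
    cross_pathway_mixing: float = 0.0  # shared-factor weight between consecutive pathways
    missing_gene_rate: float = 0.1
    lts_fraction: float = 0.2
    censor_rate: float = 0.1
    censor_short_fraction: float = 0.05  # censored before the label threshold -> excluded
    label_noise: float = 0.0
    threshold_years: float = 2.0
    age_base: float = 48.0
    age_shift: float = 13.0
    age_sd: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4 or self.n_pathways < 1:
            raise ValueError("need n_samples >= 4 and n_pathways >= 1")
        if self.genes_per_pathway < 2:
            raise ValueError("genes_per_pathway must be >= 2")
        for frac_name in ("within_pathway_rho", "cross_pathway_mixing", "missing_gene_rate",
                          "censor_rate", "censor_short_fraction", "label_noise"):
            v = getattr(self, frac_name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{frac_name} must lie in [0, 1)")
        if not (0.0 < self.lts_fraction < 1.0):
            raise ValueError("lts_fraction must lie in (0, 1)")
        if self.genes_per_pathway * (1.0 - self.missing_gene_rate) < 1.0:
            raise ValueError(
                "missing_gene_rate so high that pathways are expected to lose all genes"
            )
        for p, tag in self.signal_pathways:
            if not (0 <= p < self.n_pathways):
                raise ValueError(f"signal pathway index {p} out of range")
            if tag not in self.omics_types:
                raise ValueError(f"signal omics tag {tag!r} not among omics_types")


def _pathway_name(p: int) -> str:
    return f"PATHWAY_{p:03d}"


def signal_pathway_names(config: SyntheticConfig) -> list[str]:
    return sorted({_pathway_name(p) for p, _ in config.signal_pathways})


def generate_cohort(config: SyntheticConfig) -> tuple[list[OmicsMatrix], GeneSetCollection, ClinicalTable]:
    """Draw one cohort; identical config (incl. seed) gives bit-identical output."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_group, rng_missing, rng_omics, rng_surv, rng_age = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]

    # --- group structure -------------------------------------------------
    n_short = int(round(config.censor_short_fraction * n))
    n_rest = n - n_short
    n_lts = min(max(int(round(config.lts_fraction * n_rest)), 1), n_rest - 1)
    perm = rng_group.permutation(n)
    short_idx = perm[:n_short]
    lts_idx = perm[n_short : n_short + n_lts]
    is_short = np.zeros(n, dtype=bool)
    is_short[short_idx] = True
    is_lts = np.zeros(n, dtype=bool)
    is_lts[lts_idx] = True

    # --- gene sets --------------------------------------------------------
    pathways = []
    pathway_genes: list[list[str]] = []
    for p in range(config.n_pathways):
        genes = [f"P{p:03d}G{j:02d}" for j in range(config.genes_per_pathway)]
        pathway_genes.append(genes)
        pathways.append((_pathway_name(p), frozenset(genes)))
    gene_sets = GeneSetCollection(pathways)

    # --- omics matrices ---------------------------------------------------
    signal = set(config.signal_pathways)
    rho, mix = config.within_pathway_rho, config.cross_pathway_mixing
    omics_list = []
    for tag in config.omics_types:
        base_factors = rng_omics.standard_normal((n, config.n_pathways))
        cols, names = [], []
        for p in range(config.n_pathways):
            f = base_factors[:, p]
            if mix > 0 and p > 0:
                f = np.sqrt(1 - mix) * f + np.sqrt(mix) * base_factors[:, p - 1]
            g = config.genes_per_pathway
            eps = rng_omics.standard_normal((n, g))
            x = np.sqrt(rho) * f[:, None] + np.sqrt(1 - rho) * eps
            if (p, tag) in signal:
                x[is_lts] += config.effect_size
            keep = rng_missing.random(g) >= config.missing_gene_rate
            if not keep.any():
                keep[0] = True  # every pathway keeps at least one gene per omics
            cols.append(x[:, keep])
            names.extend([gn for gn, k in zip(pathway_genes[p], keep) if k])
        omics_list.append(
            OmicsMatrix(omics_tag=tag, sample_ids=sample_ids, gene_ids=names,
                        values=np.concatenate(cols, axis=1))
        )

    # --- survival, censoring, age ----------------------------------------
    thr = config.threshold_years
    surv_group = is_lts.copy()
    if config.label_noise > 0:
        rest = np.flatnonzero(~is_short)
        n_flip = int(round(config.label_noise * len(rest)))
        flip = rng_surv.choice(rest, size=n_flip, replace=False)
        surv_group[flip] = ~surv_group[flip]
    time = np.zeros(n)
    event = np.ones(n, dtype=int)
    # LTS: threshold + exponential tail; censoring does not hide the label
    lts_mask = surv_group & ~is_short
    time[lts_mask] = thr + rng_surv.exponential(1.5, size=lts_mask.sum())
    event[lts_mask] = (rng_surv.random(lts_mask.sum()) >= config.censor_rate).astype(int)
    # non-LTS: observed deaths within the threshold (truncated exponential)
    non_mask = ~surv_group & ~is_short
    scale = 1.2
    u = rng_surv.random(non_mask.sum())
    time[non_mask] = -scale * np.log1p(-u * (1 - np.exp(-thr / scale)))
    event[non_mask] = 1
    # short follow-up: censored before the threshold -> excluded downstream
    time[is_short] = rng_surv.uniform(0.1, thr, size=is_short.sum())
    event[is_short] = 0

    age = config.age_base + config.age_shift * (~is_lts) + rng_age.normal(0.0, config.age_sd, size=n)
    clinical = ClinicalTable(sample_id=sample_ids, survival_years=time, event=event, age=age)
    return omics_list, gene_sets, clinical


def generate_fixture() -> tuple[list[OmicsMatrix], GeneSetCollection, ClinicalTable]:
    """A tiny frozen cohort (12 samples, 5 pathways, 4 genes each) for exact
    regression tests; every call returns identical objects."""
    cfg = SyntheticConfig(
        n_samples=12,
        n_pathways=5,
        genes_per_pathway=4,
        signal_pathways=((0, "EXP"),),
        effect_size=1.5,
        within_pathway_rho=0.2,
        missing_gene_rate=0.15,
        lts_fraction=0.35,
        censor_rate=0.1,
        censor_short_fraction=0.09,
        seed=_FIXTURE_SEED,
    )
    return generate_cohort(cfg)


def write_cohort(
    omics_list, gene_sets: GeneSetCollection, clinical: ClinicalTable, outdir,
    truth: dict | None = None,
) -> dict:
    """Write a cohort to disk: one TSV per omics matrix (first column
    sample_id), gene sets as GMT, clinical table as TSV, and optionally a
    ground-truth JSON.  Returns {artifact name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for om in omics_list:
        p = outdir / f"omics_{om.omics_tag}.tsv"
        df = om.to_frame()
        df.index.name = "sample_id"
        df.to_csv(p, sep="\t", float_format="%.6g")
        paths[f"omics_{om.omics_tag}"] = str(p)
    gmt = outdir / "gene_sets.gmt"
    with open(gmt, "w") as fh:
        for name, genes in gene_sets:
            fh.write("\t".join([name, "synthetic"] + sorted(genes)) + "\n")
    paths["gene_sets"] = str(gmt)
    ctsv = outdir / "clinical.tsv"
    clinical.to_frame().to_csv(ctsv, sep="\t", index=False, float_format="%.6g")
    paths["clinical"] = str(ctsv)
    if truth is not None:
        tj = outdir / "truth.json"
        with open(tj, "w") as fh:
            json.dump(truth, fh, indent=2)
        paths["truth"] = str(tj)
    return paths
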