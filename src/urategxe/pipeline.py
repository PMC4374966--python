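"""End-to-end pipeline: simulate -> residualize -> stratified + interaction
GWAS -> genomic control -> meta-analysis -> strata-difference scans ->
circular-permutation pathway analysis.

Every stage is a plain function over in-memory tables; :func:`run_pipeline`
chains them, writes each interchange TSV under an output directory and
records a run manifest (seeds, thresholds, per-stage filter counts).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import meta as meta_mod
from . import pathways as path_mod
from . import simulate as sim_mod
from .interaction import interaction_maf_filter, run_interaction_gwas
from .residualize import residualize
from .stratified import STRATA, qc_filter, run_stratum_gwas
from .strata_diff import difference_scan


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the conventional defaults."""

    # simulation
    n_cohorts: int = 3
    n_per_cohort: int = 800
    n_snps: int = 400
    seed: int = 0
    main_effects: np.ndarray | None = None
    interaction_effects: np.ndarray | None = None
    # QC
    maf_main: float = 0.01
    maf_inter: float = 0.05
    r2hat_min: float = 0.3
    info_min: float = 0.4
    # study inclusion / dominance
    lambda_max: float = 1.2
    lambda_sensitivity: float = 1.05
    contribution_low_maf: float = 0.30
    contribution_inter: float = 0.50
    # significance
    gw_threshold: float = 5e-8
    suggestive_main: float = 1e-5
    suggestive_diff: float = 1e-5
    # pathway stage
    n_perm: int = 2000
    pathway_alpha: float = 0.05
    n_genes: int = 60
    n_pathways: int = 12
    # covariates used in residualization
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "pc1", "pc2"])

    def validate(self) -> None:
        for name in ("maf_main", "maf_inter", "r2hat_min", "info_min",
                     "contribution_low_maf", "contribution_inter",
                     "gw_threshold", "pathway_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.lambda_max <= 0 or self.lambda_sensitivity <= 0:
            raise ValueError("lambda thresholds must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k in ("main_effects", "interaction_effects"):
            if d[k] is not None:
                d[k] = [float(x) for x in d[k]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("main_effects", "interaction_effects"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def _sim_config(cfg: PipelineConfig) -> sim_mod.SimulationConfig:
    return sim_mod.SimulationConfig(
        n_cohorts=cfg.n_cohorts,
        n_per_cohort=cfg.n_per_cohort,
        n_snps=cfg.n_snps,
        main_effects=cfg.main_effects,
        interaction_effects=cfg.interaction_effects,
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig):
    cohorts, truth = sim_mod.simulate_consortium(_sim_config(cfg))
    return cohorts, truth


def stage_adjusted_traits(cohorts, cfg: PipelineConfig):
    return {
        c.cohort_id: residualize(c, cfg.covariates, sex_combined=True)
        for c in cohorts
    }


def stage_stratified(cohorts, adjusted, cfg: PipelineConfig):
    """Per-cohort per-stratum GWAS, QC, per-analysis lambda and GC correction.

    Returns (records frame stacked over analyses, per-analysis summary)."""
    frames = []
    summary = []
    for cohort in cohorts:
        for stratum in STRATA:
            rec = run_stratum_gwas(cohort, adjusted[cohort.cohort_id], stratum)
            if rec is None:
                summary.append(
                    {"cohort": cohort.cohort_id, "stratum": stratum,
                     "status": "skipped_small", "lambda": np.nan}
                )
                continue
            rec, log = qc_filter(
                rec, cfg.maf_main, cfg.r2hat_min, cfg.info_min, cohort.dialect
            )
            lam = meta_mod.genomic_lambda(rec["p"].to_numpy(), rec["analysis"].iloc[0])
            rec = meta_mod.gc_correct(rec, lam)
            frames.append(rec)
            summary.append(
                {"cohort": cohort.cohort_id, "stratum": stratum, "status": "ok",
                 "lambda": lam.lam, **{f"qc_{k}": v for k, v in log.items()}}
            )
    if not frames:
        raise RuntimeError("stratified stage produced no usable analyses")
    return pd.concat(frames, ignore_index=True), pd.DataFrame(summary)


def stage_meta(stratified_records, reference, cfg: PipelineConfig):
    """IVW meta per stratum with the dominance/low-MAF reporting filters."""
    metas = {}
    for stratum in STRATA:
        rec = stratified_records[
            stratified_records["analysis"].str.contains(f":{stratum}:")
        ]
        if rec.empty:
            continue
        m = meta_mod.ivw_meta(rec, reference=reference)
        m = meta_mod.apply_meta_filters(m, contribution_threshold=None, low_maf=True)
        metas[stratum] = m
    return metas


def stage_differences(metas, cfg: PipelineConfig):
    """All pairwise strata difference scans on filter-passing SNPs."""
    scans = {}
    for a, b in itertools.combinations(STRATA, 2):
        if a not in metas or b not in metas:
            continue
        scans[f"{a}_vs_{b}"] = difference_scan(
            metas[a][metas[a]["keep"]],
            metas[b][metas[b]["keep"]],
            report_threshold=cfg.suggestive_diff,
        )
    return scans


def stage_interaction(cohorts, adjusted, cfg: PipelineConfig, robust: bool = False,
                      lambda_max: float | None = None):
    """Per-cohort interaction GWAS, MAF filter, lambda screen, GC, IVW meta.

    Cohorts whose interaction-term lambda is at or above ``lambda_max``
    (default ``cfg.lambda_max``) are excluded from the meta, mirroring the
    inclusion rule for inflated studies. Returns (meta table, per-cohort
    summary frame).
    """
    lambda_max = cfg.lambda_max if lambda_max is None else lambda_max
    frames, summary = [], []
    for cohort in cohorts:
        rec = run_interaction_gwas(cohort, adjusted[cohort.cohort_id], robust=robust)
        rec = rec[rec["usable"]]
        rec = interaction_maf_filter(rec, cfg.maf_inter)
        lam = meta_mod.genomic_lambda(rec["p12"].to_numpy(), rec["analysis"].iloc[0])
        included = lam.lam < lambda_max
        if included:
            rec = meta_mod.gc_correct(rec, lam, se_col="se12", beta_col="beta12", p_col="p12")
            frames.append(rec)
        summary.append(
            {"cohort": cohort.cohort_id, "lambda": lam.lam, "included": included,
             "n_snps": len(rec), "robust": robust}
        )
    if not frames:
        raise RuntimeError("no cohort passed the interaction lambda screen")
    stacked = pd.concat(frames, ignore_index=True)
    m = meta_mod.ivw_meta(stacked, beta_col="beta12", se_col="se12")
    m = meta_mod.apply_meta_filters(m, contribution_threshold=cfg.contribution_inter)
    return m, pd.DataFrame(summary)


def stage_pathways(metas, reference, cfg: PipelineConfig):
    """Circular-permutation pathway test on each stratum's meta p-values."""
    rng = np.random.default_rng(cfg.seed + 9001)
    genes = sim_mod.simulate_gene_annotation(reference, n_genes=cfg.n_genes, rng=rng)
    gmt = sim_mod.simulate_pathways(
        genes["gene"], n_pathways=cfg.n_pathways, rng=rng
    )
    genome = path_mod.GenomeOrder.from_metadata(reference)
    gene_snps = path_mod.annotate_snps_to_genes(genome.snps, genes)
    sets = path_mod.build_pathway_sets(gmt, gene_snps)

    results = {}
    for stratum, m in metas.items():
        pv = m.set_index("snp")["p"].reindex(genome.snps["snp"])
        pv = pv.fillna(1.0).to_numpy()  # filtered SNPs stay on the circle, never associated
        results[stratum] = path_mod.circular_permutation_test(
            sets, pv, genome, n_perm=cfg.n_perm, alpha=cfg.pathway_alpha,
            seed=cfg.seed + 7001,
        )
    return path_mod.results_table(results), genes, gmt


# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage, write interchange TSVs + manifest, return bundle."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    def _write(df: pd.DataFrame, name: str) -> None:
        df.to_csv(outdir / name, sep="\t", index=False, na_rep="NA", float_format="%.6g")

    cohorts, truth = stage_simulate(cfg)
    for c in cohorts:
        sim_mod.write_cohort(c, outdir / "cohorts")
    _write(truth, "truth.tsv")
    reference = cohorts[0].snps

    adjusted = stage_adjusted_traits(cohorts, cfg)
    adj_rows = [
        pd.DataFrame({"cohort": cid, "id": a.values.index, "z_resid": a.values.to_numpy()})
        for cid, a in adjusted.items()
    ]
    _write(pd.concat(adj_rows, ignore_index=True), "adjusted_traits.tsv")

    strat_records, strat_summary = stage_stratified(cohorts, adjusted, cfg)
    _write(strat_records, "stratified_summary_stats.tsv")
    _write(strat_summary, "stratified_analyses.tsv")

    metas = stage_meta(strat_records, reference, cfg)
    for stratum, m in metas.items():
        _write(m, f"meta_{stratum}.tsv")

    scans = stage_differences(metas, cfg)
    scan_lambdas = {}
    for name, scan in scans.items():
        _write(scan, f"diff_{name}.tsv")
        scan_lambdas[name] = scan.attrs["lambda"]

    inter_meta, inter_summary = stage_interaction(cohorts, adjusted, cfg)
    _write(inter_meta, "meta_interaction.tsv")
    _write(inter_summary, "interaction_analyses.tsv")

    pathway_table, genes, gmt = stage_pathways(metas, reference, cfg)
    _write(pathway_table, "pathway_results.tsv")
    _write(genes, "genes.tsv")
    path_mod.write_gmt(gmt, outdir / "pathways.gmt")

    manifest = {
        "seed": cfg.seed,
        "n_cohorts": cfg.n_cohorts,
        "n_snps": cfg.n_snps,
        "thresholds": {
            "maf_main": cfg.maf_main, "maf_inter": cfg.maf_inter,
            "r2hat_min": cfg.r2hat_min, "info_min": cfg.info_min,
            "lambda_max": cfg.lambda_max,
            "lambda_sensitivity": cfg.lambda_sensitivity,
            "contribution_low_maf": cfg.contribution_low_maf,
            "contribution_inter": cfg.contribution_inter,
            "gw_threshold": cfg.gw_threshold,
        },
        "stratified_lambdas": {
            f"{row['cohort']}:{row['stratum']}": (
                None if pd.isna(row["lambda"]) else round(float(row["lambda"]), 4)
            )
            for _, row in strat_summary.iterrows()
        },
        "interaction_lambdas": {
            row["cohort"]: round(float(row["lambda"]), 4)
            for _, row in inter_summary.iterrows()
        },
        "difference_scan_lambdas": {k: round(v, 4) for k, v in scan_lambdas.items()},
        "qc_counts": strat_summary.filter(regex="^qc_|^cohort$|^stratum$").to_dict("records"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "cohorts": cohorts,
        "truth": truth,
        "adjusted": adjusted,
        "stratified": strat_records,
        "stratified_summary": strat_summary,
        "metas": metas,
        "diff_scans": scans,
        "interaction_meta": inter_meta,
        "interaction_summary": inter_summary,
        "pathways": pathway_table,
        "manifest": manifest,
    }
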