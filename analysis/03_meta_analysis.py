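#!/usr/bin/env python
"""Inverse-variance fixed-effects meta-analysis per BMI stratum.

Pools the GC-corrected per-cohort summary statistics SNP by SNP within each
stratum, computes heterogeneity (Q, I^2) and per-study weight shares, and
applies the low-MAF reporting rule (>=4 studies, no study above 30%).
"""

import argparse
from pathlib import Path

import pandas as pd

import urategxe as u
from urategxe.pipeline import stage_meta


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--rundir", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = u.PipelineConfig.from_yaml(args.rundir / "config.yaml")
    records = pd.read_csv(
        args.rundir / "stratified_summary_stats.tsv", sep="\t", na_values="NA"
    )
    reference = pd.read_csv(
        sorted((args.rundir / "cohorts").glob("*.snps.tsv"))[0], sep="\t"
    )
    metas = stage_meta(records, reference, cfg)
    for stratum, m in metas.items():
        m.to_csv(args.rundir / f"meta_{stratum}.tsv", sep="\t", index=False, na_rep="NA")
        kept = m[m["keep"]]
        lam = u.genomic_lambda(kept["p"].dropna().to_numpy()).lam
        top = kept.nsmallest(1, "p").iloc[0]
        print(
            f"{stratum}: {len(kept)}/{len(m)} SNPs reported, meta lambda {lam:.3f}; "
            f"top SNP {top['snp']} beta={top['beta']:.3f} (SE {top['se']:.3f}) "
            f"p={top['p']:.2e}"
        )
        n_gw = int((kept["p"] < cfg.gw_threshold).sum())
        if n_gw:
            print(f"  {n_gw} SNPs below the genome-wide threshold {cfg.gw_threshold:g}")


if __name__ == "__main__":
    main()
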