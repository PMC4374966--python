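#!/usr/bin/env python
"""SNP-by-BMI interaction GWAMA: classical discovery plus model-robust
follow-up, combined by inverse-variance weighting.

Cohorts are split into a discovery wave (classical OLS standard errors) and
a follow-up wave (HC0 sandwich standard errors, mirroring robust-only
software). Each wave applies the 5% MAF cut and the lambda < 1.2 inclusion
screen with genomic control, is meta-analysed separately, and the waves are
then combined; the >50% single-study dominance filter applies throughout.
A forest plot of the top combined SNP is written.
"""

import argparse
from pathlib import Path

import pandas as pd

import urategxe as u
from urategxe.pipeline import stage_interaction
from urategxe.plots import make_forest_plot
from urategxe.residualize import AdjustedTrait

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location("step02", Path(__file__).parent / "02_stratified_gwas.py")
_step02 = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_step02)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--rundir", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = u.PipelineConfig.from_yaml(args.rundir / "config.yaml")
    cohorts = _step02.load_cohorts(args.rundir)
    adj_tab = pd.read_csv(args.rundir / "adjusted_traits.tsv", sep="\t")
    adjusted = {
        cid: AdjustedTrait(cid, sub.set_index("id")["z_resid"])
        for cid, sub in adj_tab.groupby("cohort")
    }

    n_disc = max(2, (2 * len(cohorts)) // 3)
    discovery, followup = cohorts[:n_disc], cohorts[n_disc:]
    meta_d, summ_d = stage_interaction(discovery, adjusted, cfg, robust=False)
    waves = [("discovery", meta_d, summ_d)]
    if len(followup) >= 1:
        meta_f, summ_f = stage_interaction(followup, adjusted, cfg, robust=True)
        waves.append(("followup", meta_f, summ_f))

    # combine waves SNP-wise by IVW on the wave-level estimates
    stacked = pd.concat(
        [m.assign(analysis=name, n=m["n"], beta12=m["beta"], se12=m["se"])
         for name, m, _ in waves],
        ignore_index=True,
    )
    combined = u.ivw_meta(stacked, beta_col="beta12", se_col="se12")
    from urategxe.meta import apply_meta_filters

    combined = apply_meta_filters(combined, contribution_threshold=None)
    combined.to_csv(args.rundir / "meta_interaction.tsv", sep="\t", index=False, na_rep="NA")
    pd.concat([s for _, _, s in waves]).to_csv(
        args.rundir / "interaction_analyses.tsv", sep="\t", index=False
    )

    for name, m, summ in waves:
        lam = u.genomic_lambda(m["p"].dropna().to_numpy()).lam
        inc = summ.loc[summ["included"], "cohort"].tolist()
        print(f"{name}: cohorts {inc} pass lambda<{cfg.lambda_max}; wave meta lambda {lam:.3f}")
    kept = combined[combined["keep"]]
    top = kept.nsmallest(1, "p").iloc[0]
    print(
        f"combined: {len(kept)} SNPs; top interaction {top['snp']} "
        f"beta12={top['beta']:.4f} per allele per kg/m^2 (SE {top['se']:.4f}), "
        f"p={top['p']:.2e}"
    )

    per_wave = stacked[stacked["snp"] == top["snp"]][["analysis", "beta12", "se12"]]
    per_wave = per_wave.rename(columns={"beta12": "beta", "se12": "se"})
    fig = make_forest_plot(per_wave, top, title=f"interaction at {top['snp']}")
    fig.savefig(args.rundir / "interaction_top_forest.png", dpi=120)


if __name__ == "__main__":
    main()
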