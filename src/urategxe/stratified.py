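"""BMI strata assignment and per-cohort, per-stratum single-SNP association.

Strata follow the conventional BMI cut-points on the kg/m^2 scale:
lean (BMI < 25), overweight (25 <= BMI <= 30, boundaries inclusive) and
obese (BMI > 30). Within each (cohort, stratum, sex-subset) cell the
adjusted z-trait is regressed on allele dose with an intercept; p-values
come from the t distribution with n-2 degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .residualize import AdjustedTrait
from .simulate import CohortTable

STRATA = ("lean", "overweight", "obese")

#: minimum individuals in a (cohort, stratum) cell for a usable OLS fit
MIN_STRATUM_N = 30


def assign_stratum(bmi: float) -> str:
    """Label one BMI value; boundary values 25 and 30 are overweight."""
    if bmi is None or not np.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"BMI must be positive and finite, got {bmi!r}")
    if bmi < 25.0:
        return "lean"
    if bmi <= 30.0:
        return "overweight"
    return "obese"


def assign_strata(bmi: pd.Series) -> pd.Series:
    """Vectorised strata labels; non-positive/missing BMI becomes NA."""
    arr = pd.to_numeric(bmi, errors="coerce")
    out = pd.Series(pd.NA, index=bmi.index, dtype="object")
    valid = arr.notna() & (arr > 0)
    out[valid & (arr < 25.0)] = "lean"
    out[valid & (arr >= 25.0) & (arr <= 30.0)] = "overweight"
    out[valid & (arr > 30.0)] = "obese"
    return out


def _simple_ols(y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorised per-column simple regression of y on each dosage column.

    Returns (beta, se, p, zero_variance_mask); columns with zero dosage
    variance get NaN estimates.
    """
    n = len(y)
    gbar = G.mean(axis=0)
    ybar = y.mean()
    gc = G - gbar
    yc = y - ybar
    sxx = (gc * gc).sum(axis=0)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    degenerate = sxx <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(degenerate, np.nan, sxy / np.where(degenerate, 1.0, sxx))
        rss = syy - beta * sxy
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    beta[degenerate] = np.nan
    se[degenerate] = np.nan
    p[degenerate] = np.nan
    return beta, se, p, degenerate


def run_stratum_gwas(
    cohort: CohortTable,
    adjusted: AdjustedTrait,
    stratum: str,
    sex: str | None = None,
    min_n: int = MIN_STRATUM_N,
) -> pd.DataFrame | None:
    """Per-SNP OLS of the adjusted trait on allele dose within one stratum.

    ``sex`` restricts to "M"/"F"; ``None`` analyses both. Returns a
    summary-statistics frame (snp, chr, pos, A1, A2, freqA1, beta, se, p, n,
    info, analysis) or ``None`` when the cell has fewer than ``min_n``
    individuals. freqA1 is the dosage mean / 2 inside the analysed subset.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    pheno = cohort.phenotypes
    labels = assign_strata(pheno["bmi"])
    mask = (labels == stratum).to_numpy()
    if sex is not None:
        mask &= (pheno["sex"] == sex).to_numpy()
    mask &= pheno["id"].isin(adjusted.values.index).to_numpy()
    n = int(mask.sum())
    if n < min_n:
        return None

    ids = pheno.loc[mask, "id"]
    y = adjusted.values.loc[ids].to_numpy(dtype=float)
    G = cohort.dosages[mask]
    beta, se, p, _ = _simple_ols(y, G)

    tag = f"{cohort.cohort_id}:{stratum}:{sex or 'all'}"
    out = cohort.snps[["snp", "chr", "pos", "A1", "A2", "info"]].copy()
    out["freqA1"] = G.mean(axis=0) / 2.0
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n
    out["analysis"] = tag
    return out[
        ["snp", "chr", "pos", "A1", "A2", "freqA1", "beta", "se", "p", "n", "info", "analysis"]
    ]


def qc_filter(
    records: pd.DataFrame,
    maf_min: float = 0.01,
    info_min_mach: float = 0.3,
    info_min_impute: float = 0.4,
    dialect: str = "mach",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop low-MAF, poorly imputed, and failed-fit records.

    A record fails when maf < maf_min, when its imputation-quality metric is
    below the dialect's threshold (r2hat for MACH, info for IMPUTE), or when
    the regression produced no usable estimate. Returns the retained frame
    and counts of exclusions by reason.
    """
    for thr in (maf_min, info_min_mach, info_min_impute):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("QC thresholds must be in [0,1]")
    if dialect not in ("mach", "impute"):
        raise ValueError(f"unknown imputation dialect {dialect!r}")
    info_min = info_min_mach if dialect == "mach" else info_min_impute

    maf = np.minimum(records["freqA1"], 1.0 - records["freqA1"])
    fail_maf = maf < maf_min
    fail_info = records["info"] < info_min
    fail_fit = records["beta"].isna() | records["se"].isna() | (records["se"] <= 0)
    drop = fail_maf | fail_info | fail_fit
    log = {
        "input": len(records),
        "low_maf": int(fail_maf.sum()),
        "low_info": int((fail_info & ~fail_maf).sum()),
        "failed_fit": int((fail_fit & ~fail_maf & ~fail_info).sum()),
        "retained": int((~drop).sum()),
    }
    return records.loc[~drop].copy(), log
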