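"""SNP-by-BMI interaction regression on the non-stratified sample.

Per SNP, the model is

    z(residual) ~ mu + beta1*BMI + beta2*dose + beta12*BMI*dose + eps

with BMI continuous and uncentered by default. The interaction standard
error comes either from the classical OLS covariance or, in the
model-robust branch, from the heteroskedasticity-consistent HC0 sandwich
(X'X)^-1 X'diag(e^2)X (X'X)^-1. The fit is vectorised across SNPs through
the cross-product sums that the 4x4 normal equations need, so a
genome-wide scan is a handful of matrix products.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .residualize import AdjustedTrait
from .simulate import CohortTable

#: minimum complete rows for the interaction fit
MIN_INTERACTION_N = 50


def interaction_fit(
    y: np.ndarray,
    bmi: np.ndarray,
    G: np.ndarray,
    robust: bool = False,
    center_bmi: bool = False,
) -> dict[str, np.ndarray]:
    """Fit the interaction model for every dosage column at once.

    Returns arrays keyed beta0/beta1/beta2/beta12/se12/p12/usable. With
    ``center_bmi`` the design uses BMI - mean(BMI) for conditioning and the
    intercept/SNP coefficients are mapped back to the uncentered
    parameterisation (beta12 and its SE are invariant to centering).
    """
    y = np.asarray(y, dtype=float)
    bmi_raw = np.asarray(bmi, dtype=float)
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    if len(y) != n or len(bmi_raw) != n:
        raise ValueError("y, bmi and dosage rows must align")
    if n < 5:
        raise ValueError("need at least 5 rows to fit 4 coefficients")

    c = bmi_raw.mean() if center_bmi else 0.0
    b = bmi_raw - c
    b2 = b * b

    usable = (G.std(axis=0) > 0) & np.full(m, b.std() > 0)

    # cross products for X = [1, b, g, b*g] per SNP
    G2 = G * G
    s1g = G.sum(axis=0)
    sbg = b @ G
    sb2g = b2 @ G
    sg2 = G2.sum(axis=0)
    sbg2 = b @ G2
    sb2g2 = b2 @ G2
    sy = y.sum()
    sby = b @ y
    sgy = y @ G
    sbgy = (b * y) @ G
    sb = b.sum()
    sb2 = b2.sum()
    syy = float(y @ y)

    xtx = np.empty((m, 4, 4))
    xtx[:, 0, 0] = n
    xtx[:, 0, 1] = xtx[:, 1, 0] = sb
    xtx[:, 1, 1] = sb2
    xtx[:, 0, 2] = xtx[:, 2, 0] = s1g
    xtx[:, 0, 3] = xtx[:, 3, 0] = sbg
    xtx[:, 1, 2] = xtx[:, 2, 1] = sbg
    xtx[:, 1, 3] = xtx[:, 3, 1] = sb2g
    xtx[:, 2, 2] = sg2
    xtx[:, 2, 3] = xtx[:, 3, 2] = sbg2
    xtx[:, 3, 3] = sb2g2
    xty = np.stack([np.full(m, sy), np.full(m, sby), sgy, sbgy], axis=1)

    beta = np.full((m, 4), np.nan)
    se12 = np.full(m, np.nan)
    p12 = np.full(m, np.nan)
    ok = usable.copy()
    if ok.any():
        xtx_ok = xtx[ok]
        try:
            inv = np.linalg.inv(xtx_ok)
        except np.linalg.LinAlgError:
            inv = np.linalg.pinv(xtx_ok)
        beta_ok = np.einsum("mij,mj->mi", inv, xty[ok])
        beta[ok] = beta_ok

        if robust:
            # HC0 meat: sum_i e_i^2 x_i x_i' assembled from b^k * g^l moments
            fitted = (
                beta[:, 0][None, :]
                + np.outer(b, beta[:, 1])
                + G * (beta[:, 2][None, :] + np.outer(b, beta[:, 3]))
            )
            W = (y[:, None] - fitted) ** 2
            WG = W * G
            WG2 = W * G2
            mom = {}
            for k, bk in ((0, np.ones(n)), (1, b), (2, b2)):
                mom[(k, 0)] = bk @ W
                mom[(k, 1)] = bk @ WG
                mom[(k, 2)] = bk @ WG2
            powers = [(0, 0), (1, 0), (0, 1), (1, 1)]  # (b-power, g-power) of each column
            meat = np.empty((m, 4, 4))
            for a in range(4):
                for bb in range(a, 4):
                    ka, la = powers[a]
                    kb, lb = powers[bb]
                    meat[:, a, bb] = meat[:, bb, a] = mom[(ka + kb, la + lb)]
            cov = np.einsum("mij,mjk,mkl->mil", inv, meat[ok], inv)
            se12[ok] = np.sqrt(np.maximum(cov[:, 3, 3], 0.0))
            with np.errstate(invalid="ignore", divide="ignore"):
                z = beta[ok, 3] / se12[ok]
            p12[ok] = 2.0 * stats.norm.sf(np.abs(z))
        else:
            rss = syy - np.einsum("mi,mi->m", beta_ok, xty[ok])
            sigma2 = np.maximum(rss, 0.0) / (n - 4)
            se12[ok] = np.sqrt(np.maximum(inv[:, 3, 3], 0.0) * sigma2)
            with np.errstate(invalid="ignore", divide="ignore"):
                t = beta[ok, 3] / se12[ok]
            p12[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 4)

    if center_bmi:
        # map back: with b = BMI - c, beta2_uncentered = beta2 - c*beta12,
        # beta0_uncentered = beta0 - c*beta1; beta1 and beta12 unchanged
        beta_unc = beta.copy()
        beta_unc[:, 0] = beta[:, 0] - c * beta[:, 1]
        beta_unc[:, 2] = beta[:, 2] - c * beta[:, 3]
        beta = beta_unc

    resid_sd = np.full(m, np.nan)
    if ok.any() and not robust:
        resid_sd[ok] = np.sqrt(sigma2)
    return {
        "beta0": beta[:, 0],
        "beta1": beta[:, 1],
        "beta2": beta[:, 2],
        "beta12": beta[:, 3],
        "se12": se12,
        "p12": p12,
        "usable": usable,
        "resid_sd": resid_sd,
    }


def run_interaction_gwas(
    cohort: CohortTable,
    adjusted: AdjustedTrait,
    robust: bool = False,
    center_bmi: bool = False,
    min_n: int = MIN_INTERACTION_N,
) -> pd.DataFrame:
    """Per-SNP interaction scan for one cohort.

    Mirrors the reporting convention of robust-only software: the BMI and
    SNP main-effect coefficients are withheld (NA) in the robust branch,
    which reports only the interaction term.
    """
    pheno = cohort.phenotypes
    mask = (
        pheno["id"].isin(adjusted.values.index)
        & pheno["bmi"].notna()
        & (pheno["bmi"] > 0)
    ).to_numpy()
    n = int(mask.sum())
    if n < min_n:
        raise ValueError(
            f"{cohort.cohort_id}: only {n} complete rows; need >= {min_n}"
        )
    ids = pheno.loc[mask, "id"]
    y = adjusted.values.loc[ids].to_numpy(dtype=float)
    bmi = pheno.loc[mask, "bmi"].to_numpy(dtype=float)
    G = cohort.dosages[mask]

    fit = interaction_fit(y, bmi, G, robust=robust, center_bmi=center_bmi)
    out = cohort.snps[["snp", "chr", "pos", "A1", "A2", "info"]].copy()
    out["freqA1"] = G.mean(axis=0) / 2.0
    out["beta1"] = np.nan if robust else fit["beta1"]
    out["beta2"] = np.nan if robust else fit["beta2"]
    out["beta12"] = fit["beta12"]
    out["se12"] = fit["se12"]
    out["p12"] = fit["p12"]
    out["n"] = n
    out["robust"] = bool(robust)
    out["resid_sd"] = fit["resid_sd"]
    out["usable"] = fit["usable"]
    out["analysis"] = f"{cohort.cohort_id}:interaction:{'robust' if robust else 'classical'}"
    return out


def interaction_maf_filter(
    records: pd.DataFrame, maf_min: float = 0.05
) -> pd.DataFrame:
    """Apply the stricter interaction-analysis MAF cut-off (drop maf < cut)."""
    maf = np.minimum(records["freqA1"], 1.0 - records["freqA1"])
    return records.loc[maf >= maf_min].copy()
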