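"""Between-strata effect-difference testing.

For a SNP with meta-analysed effects (beta_a, se_a) and (beta_b, se_b) in
two BMI strata, the difference statistic is

    t = (beta_a - beta_b) / sqrt(se_a^2 + se_b^2 - 2*r*se_a*se_b)

where r is the Spearman rank correlation between the two strata's
beta-estimates across all shared SNPs, estimated once per comparison and
applied to every SNP. Under no difference t is referred to the standard
normal by default (a Student t reference with chosen df is available);
the genome-wide scan also reports the genomic-control lambda of the
squared statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .meta import CHI2_MEDIAN_1DF


def cross_strata_correlation(betas_a: np.ndarray, betas_b: np.ndarray) -> float:
    """Spearman correlation of per-SNP effect estimates between two strata."""
    a = np.asarray(betas_a, dtype=float)
    b = np.asarray(betas_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("beta vectors must be aligned on the same SNPs")
    if a.size < 3:
        raise ValueError(f"need at least 3 shared SNPs, got {a.size}")
    r = stats.spearmanr(a, b).statistic
    return float(r)


def difference_test(
    beta_a: float | np.ndarray,
    se_a: float | np.ndarray,
    beta_b: float | np.ndarray,
    se_b: float | np.ndarray,
    r: float,
    df: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided test of beta_a == beta_b given correlated SEs.

    Returns (t, p). Where the two estimates are identical, t = 0 and p = 1
    even when the variance of the difference degenerates (the r -> 1 same
    input guard); a non-positive variance with a non-zero numerator is an
    error. ``df=None`` uses the standard normal reference.
    """
    beta_a = np.asarray(beta_a, dtype=float)
    beta_b = np.asarray(beta_b, dtype=float)
    se_a = np.asarray(se_a, dtype=float)
    se_b = np.asarray(se_b, dtype=float)
    if np.any(se_a <= 0) or np.any(se_b <= 0):
        raise ValueError("standard errors must be positive")
    var = se_a**2 + se_b**2 - 2.0 * r * se_a * se_b
    num = beta_a - beta_b
    bad = (var <= 0) & (num != 0)
    if np.any(bad):
        raise ValueError(
            "non-positive variance of the effect difference; "
            "check r and the standard errors"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(num == 0, 0.0, num / np.sqrt(np.where(var > 0, var, 1.0)))
    if df is None:
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df)
    if np.ndim(beta_a) == 0:
        return float(t), float(p)
    return t, p


def ci_two_se(beta: float, se: float) -> tuple[float, float]:
    """Plus/minus two standard errors, the reporting convention for 95% CIs."""
    if se < 0:
        raise ValueError("se must be non-negative")
    return beta - 2.0 * se, beta + 2.0 * se


def difference_scan(
    meta_a: pd.DataFrame,
    meta_b: pd.DataFrame,
    report_threshold: float = 1e-5,
    df: int | None = None,
    min_shared: int = 100,
) -> pd.DataFrame:
    """Genome-wide effect-difference scan between two stratum meta tables.

    Shares SNPs by id; r is the Spearman correlation over the full shared,
    usable set; every SNP is then tested with that r. Output is sorted by
    p_diff, flags rows below ``report_threshold`` and carries the scan's
    genomic-control lambda (median of t^2 over the chi-square(1) median) in
    ``attrs["lambda"]``.
    """
    cols = ["snp", "beta", "se"]
    a = meta_a[cols + [c for c in ("chr", "pos") if c in meta_a.columns]].rename(
        columns={"beta": "beta_a", "se": "se_a"}
    )
    b = meta_b[cols].rename(columns={"beta": "beta_b", "se": "se_b"})
    merged = a.merge(b, on="snp", how="inner")
    merged = merged.dropna(subset=["beta_a", "se_a", "beta_b", "se_b"])
    merged = merged[(merged["se_a"] > 0) & (merged["se_b"] > 0)]
    if len(merged) == 0:
        raise ValueError("the two meta tables share no usable SNPs")
    if len(merged) < min_shared:
        raise ValueError(
            f"only {len(merged)} shared SNPs; need >= {min_shared} for a genome-wide scan"
        )

    r = cross_strata_correlation(
        merged["beta_a"].to_numpy(), merged["beta_b"].to_numpy()
    )
    # an r estimated as exactly +/-1 (identical tables) would degenerate the
    # variance; the identical-beta rows are guarded inside difference_test
    t, p = difference_test(
        merged["beta_a"].to_numpy(),
        merged["se_a"].to_numpy(),
        merged["beta_b"].to_numpy(),
        merged["se_b"].to_numpy(),
        r,
        df=df,
    )
    merged["r"] = r
    merged["t"] = t
    merged["p_diff"] = p
    merged["significant"] = merged["p_diff"] < report_threshold
    merged = merged.sort_values("p_diff", kind="mergesort").reset_index(drop=True)
    merged.attrs["lambda"] = float(np.median(np.asarray(t) ** 2) / CHI2_MEDIAN_1DF)
    merged.attrs["r"] = r
    return merged


def candidate_bonferroni(n_snps: int, n_comparisons: int, fwer: float = 0.05) -> float:
    """Bonferroni threshold for a candidate-SNP strata-difference screen."""
    if n_snps < 1 or n_comparisons < 1:
        raise ValueError("counts must be >= 1")
    return fwer / (n_snps * n_comparisons)
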