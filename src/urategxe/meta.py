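"""Genomic control, inverse-variance fixed-effects meta-analysis and the
study-dominance filters.

Per-study results are genomic-control corrected (SE scaled by sqrt(lambda)
when lambda > 1) before pooling; the pooled SE and p-value are not corrected
again. Pooling uses fixed-effects inverse-variance weights w_i = 1/SE_i^2,
with Cochran's Q and I^2 for heterogeneity and per-study weight shares for
the dominance filters (drop when one study contributes more than 50%; for
low-MAF stratified results require at least four studies and no study above
30%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.454936...

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class InflationEstimate:
    analysis: str
    lam: float
    n_tests: int


def genomic_lambda(pvalues: np.ndarray, analysis: str = "") -> InflationEstimate:
    """Genomic-control inflation factor from two-sided p-values.

    lambda = median of the implied 1-df chi-square statistics divided by the
    chi-square(1) median (~0.4549). Fewer than 100 p-values triggers a
    warning but lambda is still computed.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0 or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size < 100:
        warnings.warn(
            f"genomic_lambda on only {p.size} p-values; estimate is unstable",
            stacklevel=2,
        )
    chi2 = stats.chi2.isf(p, df=1)
    return InflationEstimate(analysis, float(np.median(chi2) / CHI2_MEDIAN_1DF), p.size)


def gc_correct(
    records: pd.DataFrame,
    lam: float | InflationEstimate,
    se_col: str = "se",
    beta_col: str = "beta",
    p_col: str = "p",
) -> pd.DataFrame:
    """Apply genomic control to one study's summary statistics.

    When lambda > 1 the SEs are multiplied by sqrt(lambda) and p-values are
    recomputed from the corrected z; betas are untouched. lambda <= 1 is the
    identity (no deflation).
    """
    if isinstance(lam, InflationEstimate):
        lam = lam.lam
    if lam <= 1.0:
        return records.copy()
    out = records.copy()
    out[se_col] = records[se_col] * np.sqrt(lam)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = out[beta_col] / out[se_col]
    out[p_col] = 2.0 * stats.norm.sf(np.abs(z))
    return out


# ---------------------------------------------------------------------------
# allele alignment


def align_alleles(
    records: pd.DataFrame,
    reference: pd.DataFrame,
    beta_cols: tuple[str, ...] = ("beta",),
    ambiguous_maf_max: float = 0.4,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Orient one study's records onto reference A1/A2.

    Straight matches pass through; A1/A2 swaps flip the beta sign(s) and the
    frequency. Strand flips are resolved through allele complements.
    Strand-ambiguous SNPs (A/T, C/G) are aligned by frequency when
    maf < ``ambiguous_maf_max`` and dropped otherwise; irreconcilable allele
    pairs are dropped and counted in the log.
    """
    ref = reference.set_index("snp")[["A1", "A2"]].rename(
        columns={"A1": "refA1", "A2": "refA2"}
    )
    if "freqA1" in reference.columns:
        ref["ref_freq"] = reference.set_index("snp")["freqA1"]
    df = records.join(ref, on="snp")
    unknown = df["refA1"].isna()

    a1 = df["A1"].str.upper()
    a2 = df["A2"].str.upper()
    r1 = df["refA1"].astype("string").str.upper()
    r2 = df["refA2"].astype("string").str.upper()
    c1 = a1.map(_COMPLEMENT)
    c2 = a2.map(_COMPLEMENT)

    same = (a1 == r1) & (a2 == r2)
    swap = (a1 == r2) & (a2 == r1)
    strand_same = (c1 == r1) & (c2 == r2)
    strand_swap = (c1 == r2) & (c2 == r1)
    ambiguous = a1 == c2  # A/T or C/G pair: strand flip indistinguishable from swap

    keep_as_is = (same | strand_same) & ~ambiguous
    flip = (swap | strand_swap) & ~ambiguous
    freq = df["freqA1"].to_numpy(dtype=float)
    maf = np.minimum(freq, 1.0 - freq)
    amb_resolvable = ambiguous & (same | swap | strand_same | strand_swap)
    if "ref_freq" in df.columns:
        amb_ok = amb_resolvable & (maf < ambiguous_maf_max)
        ref_freq = df["ref_freq"].to_numpy(dtype=float)
        # frequency alignment: flip when the frequencies sit on opposite sides of 0.5
        amb_flip = amb_ok & ((freq - 0.5) * (ref_freq - 0.5) < 0)
        keep_as_is = keep_as_is | (amb_ok & ~amb_flip)
        flip = flip | amb_flip
    mismatch = ~(keep_as_is | flip) & ~unknown

    out = df.copy()
    flip_arr = flip.to_numpy()
    for col in beta_cols:
        out.loc[flip_arr, col] = -out.loc[flip_arr, col]
    out.loc[flip_arr, "freqA1"] = 1.0 - out.loc[flip_arr, "freqA1"]
    out["A1"] = out["refA1"].where(~unknown, out["A1"])
    out["A2"] = out["refA2"].where(~unknown, out["A2"])
    kept = out.loc[(keep_as_is | flip) & ~unknown].drop(
        columns=[c for c in ("refA1", "refA2", "ref_freq") if c in out.columns]
    )
    log = {
        "input": len(records),
        "flipped": int(flip_arr.sum()),
        "dropped_mismatch": int(mismatch.sum()),
        "dropped_unknown_snp": int(unknown.sum()),
        "retained": len(kept),
    }
    return kept, log


# ---------------------------------------------------------------------------
# inverse-variance pooling


def ivw_combine(betas: np.ndarray, ses: np.ndarray) -> dict[str, np.ndarray]:
    """Fixed-effects IVW pooling, vectorised over SNP columns.

    ``betas``/``ses`` are studies x SNPs; NaN or non-finite entries (and
    infinite SEs, which carry zero weight) are ignored per SNP. Returns
    beta, se, p (two-sided normal), n_studies, Q, I2 (percent), and
    max_contribution = max_i w_i / sum w.
    """
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    ses = np.atleast_2d(np.asarray(ses, dtype=float))
    if betas.shape != ses.shape:
        raise ValueError("betas and ses must have the same shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 / (ses * ses)
    valid = np.isfinite(betas) & np.isfinite(ses) & (ses > 0) & np.isfinite(w)
    w = np.where(valid, w, 0.0)
    b = np.where(valid, betas, 0.0)

    wsum = w.sum(axis=0)
    k = valid.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (w * b).sum(axis=0) / wsum
        se = np.sqrt(1.0 / wsum)
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        q = (w * (b - beta[None, :]) ** 2).sum(axis=0)
        i2 = np.where(q > 0, np.maximum(0.0, (q - (k - 1)) / np.where(q > 0, q, 1.0)) * 100.0, 0.0)
        contrib = np.where(wsum > 0, w / wsum, 0.0)
        max_contrib = contrib.max(axis=0)
    none = k == 0
    for arr in (beta, se, p, q, i2, max_contrib):
        arr[none] = np.nan
    return {
        "beta": beta,
        "se": se,
        "p": p,
        "n_studies": k,
        "Q": q,
        "I2": i2,
        "max_contribution": max_contrib,
        "contributions": contrib,
    }


def ivw_meta(
    records: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    beta_col: str = "beta",
    se_col: str = "se",
) -> pd.DataFrame:
    """Meta-analyse stacked per-study summary statistics.

    ``records`` holds one row per (study analysis, SNP) with at least
    (snp, A1, A2, freqA1, beta_col, se_col, n, analysis). When ``reference``
    SNP metadata is given, each study is first oriented onto its alleles.
    Returns one row per SNP with the pooled estimate, heterogeneity and the
    maximum study contribution.
    """
    df = records
    align_log: dict[str, int] = {}
    if reference is not None:
        df, align_log = align_alleles(df, reference, beta_cols=(beta_col,))

    snps = df["snp"].unique()
    order = pd.Index(snps)
    studies = df["analysis"].unique()
    B = np.full((len(studies), len(order)), np.nan)
    S = np.full((len(studies), len(order)), np.nan)
    N = np.zeros((len(studies), len(order)))
    F = np.full((len(studies), len(order)), np.nan)
    srow = {s: i for i, s in enumerate(studies)}
    ci = order.get_indexer(df["snp"])
    ri = df["analysis"].map(srow).to_numpy()
    B[ri, ci] = df[beta_col].to_numpy(dtype=float)
    S[ri, ci] = df[se_col].to_numpy(dtype=float)
    N[ri, ci] = df["n"].to_numpy(dtype=float)
    F[ri, ci] = df["freqA1"].to_numpy(dtype=float)

    res = ivw_combine(B, S)
    valid = np.isfinite(B) & np.isfinite(S) & (S > 0)
    n_total = np.where(valid, N, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(np.where(valid, F * N, 0.0), axis=0) / np.where(
            n_total > 0, n_total, np.nan
        )

    meta_cols = df.drop_duplicates("snp").set_index("snp")
    out = pd.DataFrame(
        {
            "snp": order,
            "chr": meta_cols["chr"].reindex(order).to_numpy() if "chr" in meta_cols else np.nan,
            "pos": meta_cols["pos"].reindex(order).to_numpy() if "pos" in meta_cols else np.nan,
            "A1": meta_cols["A1"].reindex(order).to_numpy(),
            "A2": meta_cols["A2"].reindex(order).to_numpy(),
            "freqA1": freq,
            "beta": res["beta"],
            "se": res["se"],
            "p": res["p"],
            "n_studies": res["n_studies"],
            "n": n_total,
            "Q": res["Q"],
            "I2": res["I2"],
            "max_contribution": res["max_contribution"],
        }
    )
    out.attrs["align_log"] = align_log
    return out


def meta_record(betas, ses) -> dict[str, float]:
    """IVW pooling of one SNP given per-study (beta, se) sequences."""
    res = ivw_combine(np.asarray(betas)[:, None], np.asarray(ses)[:, None])
    return {k: (v[:, 0] if k == "contributions" else float(np.asarray(v)[0])) for k, v in res.items()}


# ---------------------------------------------------------------------------
# dominance / reporting filters


def contribution_filter(max_contribution: float, threshold: float = 0.5) -> bool:
    """Keep unless one study's weight share strictly exceeds the threshold."""
    return not (max_contribution > threshold)


def low_maf_rule(
    maf: float,
    n_studies: int,
    max_contribution: float,
    maf_threshold: float = 0.05,
    min_studies: int = 4,
    contribution_max: float = 0.30,
) -> bool:
    """Reporting rule for low-frequency stratified meta results.

    Below the MAF threshold a pooled result is kept only when at least
    ``min_studies`` studies contributed and no single study's weight share
    exceeds ``contribution_max``; at or above the threshold the rule does
    not apply (returns True).
    """
    if maf >= maf_threshold:
        return True
    return n_studies >= min_studies and not (max_contribution > contribution_max)


def apply_meta_filters(
    meta: pd.DataFrame,
    contribution_threshold: float | None = 0.5,
    low_maf: bool = False,
) -> pd.DataFrame:
    """Annotate a meta table with keep/drop flags.

    ``contribution_threshold=None`` skips the dominance filter (it applies
    to the interaction meta; stratified main-effect metas use only the
    low-MAF reporting rule).
    """
    out = meta.copy()
    if contribution_threshold is None:
        out["keep_contribution"] = True
    else:
        out["keep_contribution"] = [
            contribution_filter(mc, contribution_threshold)
            for mc in out["max_contribution"]
        ]
    if low_maf:
        maf = np.minimum(out["freqA1"], 1.0 - out["freqA1"])
        out["keep_low_maf"] = [
            low_maf_rule(f, int(k), mc)
            for f, k, mc in zip(maf, out["n_studies"], out["max_contribution"])
        ]
    else:
        out["keep_low_maf"] = True
    out["keep"] = out["keep_contribution"] & out["keep_low_maf"]
    return out
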