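"""QQ and forest plots for GWAS summary and meta-analysis results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .meta import CHI2_MEDIAN_1DF, genomic_lambda


def make_qq_plot(values: np.ndarray, kind: str = "p", ax=None, title: str = ""):
    """Observed-vs-expected quantile plot with a lambda annotation.

    ``kind="p"`` plots -log10 p-values against Uniform(0,1) expectations;
    ``kind="chisq"`` plots sorted 1-df chi-square statistics (e.g. squared
    difference-scan statistics) against chi-square(1) quantiles. Returns
    (figure, lambda).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 100:
        raise ValueError(f"need at least 100 values for a QQ plot, got {v.size}")
    if ax is None:
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
    else:
        fig = ax.figure

    n = v.size
    if kind == "p":
        lam = genomic_lambda(v).lam
        obs = -np.log10(np.sort(v))
        exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
        label = "-log10(p)"
    elif kind == "chisq":
        lam = float(np.median(v) / CHI2_MEDIAN_1DF)
        obs = np.sort(v)
        exp = stats.chi2.ppf((np.arange(1, n + 1) - 0.5) / n, df=1)
        label = "chi-square (1 df)"
    else:
        raise ValueError(f"unknown QQ kind {kind!r}")

    ax.plot(np.sort(exp), obs, ".", ms=3, color="steelblue")
    lim = max(exp.max(), obs.max())
    ax.plot([0, lim], [0, lim], "-", lw=1, color="grey")
    ax.set_xlabel(f"expected {label}")
    ax.set_ylabel(f"observed {label}")
    ax.text(0.05, 0.92, f"$\\lambda$ = {lam:.4f}", transform=ax.transAxes)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig, lam


def make_forest_plot(studies, meta_row, title: str = ""):
    """Forest plot: per-study estimates with +/-2SE bars and the pooled diamond.

    ``studies`` is a frame with columns (analysis, beta, se); ``meta_row``
    is a mapping with beta, se, I2 and optionally Q. The pooled estimate is
    drawn as a diamond whose width spans +/-2SE, annotated with I^2.
    """
    studies = studies.dropna(subset=["beta", "se"])
    if len(studies) < 1:
        raise ValueError("need at least one study to draw a forest plot")
    k = len(studies)
    fig, ax = plt.subplots(figsize=(5.5, 0.5 * k + 1.8))
    ys = np.arange(k, 0, -1)
    ax.errorbar(
        studies["beta"], ys, xerr=2.0 * studies["se"],
        fmt="s", color="black", ms=4, capsize=2, lw=1,
    )
    for y, name in zip(ys, studies["analysis"]):
        ax.text(-0.02, y, str(name), transform=ax.get_yaxis_transform(),
                ha="right", va="center", fontsize=8)

    b, s = float(meta_row["beta"]), float(meta_row["se"])
    diamond_x = [b - 2 * s, b, b + 2 * s, b]
    diamond_y = [0, 0.25, 0, -0.25]
    ax.fill(diamond_x, diamond_y, color="firebrick")
    i2 = float(meta_row.get("I2", np.nan))
    q = meta_row.get("Q", None)
    note = f"pooled: {b:.3f}  I$^2$ = {i2:.0f}%"
    if q is not None and np.isfinite(q) and k > 1:
        het_p = stats.chi2.sf(float(q), df=k - 1)
        note += f", het. p = {het_p:.2g}"
    ax.text(0.02, 0.02, note, transform=ax.transAxes, fontsize=8)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks([])
    ax.set_ylim(-0.8, k + 0.8)
    ax.set_xlabel("effect on z-scored urate per allele")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig
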