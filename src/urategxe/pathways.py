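"""Circular genomic permutation pathway analysis.

The genome (chromosomes 1..22 joined end to end) is treated as a circle of
M analysed SNPs in genome order. A pathway's observed statistic is the
number of its SNPs with association p <= alpha. Each permutation rotates
the p-value vector by a random non-zero offset while SNP labels and
positions stay fixed, preserving the local correlation structure; the
empirical pathway p-value is the fraction of rotations with at least as
many associated SNPs as observed (a strict "more than" convention is
available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class GenomeOrder:
    """Analysed SNPs sorted by (chr, pos), indexed 0..M-1 on a circle."""

    snps: pd.DataFrame  # columns snp, chr, pos, sorted

    @classmethod
    def from_metadata(cls, snps: pd.DataFrame) -> "GenomeOrder":
        df = snps[["snp", "chr", "pos"]].copy()
        if df["snp"].duplicated().any():
            raise ValueError("duplicate SNP ids in genome order")
        df = df.sort_values(["chr", "pos"], kind="mergesort").reset_index(drop=True)
        within = df.groupby("chr")["pos"].diff()
        if (within <= 0).any():
            raise ValueError("SNP positions must be strictly increasing within a chromosome")
        return cls(df)

    def __len__(self) -> int:
        return len(self.snps)

    def index_of(self, snp_ids) -> np.ndarray:
        idx = pd.Index(self.snps["snp"]).get_indexer(snp_ids)
        if (idx < 0).any():
            raise KeyError("some SNPs are not in the genome order")
        return idx


@dataclass
class PathwaySet:
    pathway_id: str
    genes: list[str]
    snp_indices: np.ndarray  # unique indices into GenomeOrder


@dataclass
class PermutationResult:
    pathway_id: str
    n_genes: int
    n_snps: int
    observed_count: int
    empirical_p: float
    perm_counts: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# annotation


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: one set per line (name, description, genes...)."""
    out: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_gmt(pathways: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def read_gene_intervals(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read gene intervals as 1-based inclusive (chr, start, end).

    ``dialect="tsv"`` expects columns (gene, chr, start, end) already
    1-based inclusive; ``dialect="bed"`` reads 0-based half-open BED
    (chrom, chromStart, chromEnd, name) and converts start -> start+1.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        need = {"gene", "chr", "start", "end"}
        if not need.issubset(df.columns):
            raise ValueError(f"gene interval TSV must have columns {sorted(need)}")
        return df[["gene", "chr", "start", "end"]].copy()
    if dialect == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chr", "start", "end", "gene"],
            usecols=[0, 1, 2, 3],
        )
        df["chr"] = df["chr"].astype(str).str.removeprefix("chr").astype(int)
        df["start"] = df["start"] + 1  # BED half-open, 0-based -> 1-based inclusive
        return df[["gene", "chr", "start", "end"]]
    raise ValueError(f"unknown gene-interval dialect {dialect!r}")


def annotate_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Map each gene to the genome-order indices of the SNPs it contains.

    Intervals are 1-based inclusive; a SNP inside several overlapping genes
    maps to all of them. SNPs outside every gene stay in the genome order
    but belong to no gene.
    """
    if (genes["start"] > genes["end"]).any():
        bad = genes.loc[genes["start"] > genes["end"], "gene"].tolist()
        raise ValueError(f"gene intervals with start > end: {bad}")
    order = snps.sort_values(["chr", "pos"], kind="mergesort").reset_index(drop=True)
    out: dict[str, np.ndarray] = {}
    for chrom, sub in genes.groupby("chr"):
        chrom_snps = order[order["chr"] == chrom]
        pos = chrom_snps["pos"].to_numpy()
        base = chrom_snps.index.to_numpy()
        lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="right")
        for g, a, b in zip(sub["gene"], lo, hi):
            out[g] = base[a:b]
    for g in genes["gene"]:
        out.setdefault(g, np.empty(0, dtype=int))
    return out


def build_pathway_sets(
    pathways: dict[str, list[str]], gene_snps: dict[str, np.ndarray]
) -> list[PathwaySet]:
    """Resolve gene sets into unique per-pathway SNP indices."""
    sets = []
    for pid, genes in pathways.items():
        idx = np.unique(
            np.concatenate(
                [gene_snps.get(g, np.empty(0, dtype=int)) for g in genes]
                or [np.empty(0, dtype=int)]
            )
        ).astype(int)
        sets.append(PathwaySet(pid, list(genes), idx))
    return sets


# ---------------------------------------------------------------------------
# the permutation test


def observed_count(
    snp_indices: np.ndarray, pvalues: np.ndarray, alpha: float = 0.05
) -> int:
    """Associated-SNP count: pathway SNPs with p <= alpha (boundary counted)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any(~np.isfinite(p[snp_indices])):
        raise ValueError("pathway SNPs carry missing p-values")
    return int((p[snp_indices] <= alpha).sum())


def _offsets(M: int, n_perm: int, rng: np.random.Generator, exhaustive: bool) -> np.ndarray:
    all_offsets = np.arange(1, M)  # identity rotation excluded
    if exhaustive or n_perm >= M - 1:
        return all_offsets
    return rng.choice(all_offsets, size=n_perm, replace=True)


def circular_permutation_test(
    pathways: list[PathwaySet],
    pvalues: np.ndarray,
    genome: GenomeOrder,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    exhaustive: bool = False,
    strict: bool = False,
    keep_perm_counts: bool = False,
) -> list[PermutationResult]:
    """Empirical pathway p-values from circular rotations of the p-vector.

    ``pvalues`` must be aligned to ``genome`` order. Rotation by offset d
    assigns the p-value originally at circle position (i - d) mod M to
    position i. With ``exhaustive`` (or n_perm >= M-1) every distinct
    non-identity rotation is used exactly once; otherwise offsets are drawn
    with replacement. ``strict`` counts only rotations with strictly more
    associated SNPs (the default counts ties, so a pathway with observed
    count 0 has empirical p = 1).
    """
    M = len(genome)
    p = np.asarray(pvalues, dtype=float)
    if p.shape != (M,):
        raise ValueError("pvalues must align with the genome order")
    if M < 2:
        raise ValueError("need at least 2 SNPs on the circle")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    offsets = _offsets(M, n_perm, rng, exhaustive)
    assoc = (p <= alpha).astype(np.int8)

    results = []
    for ps in pathways:
        obs = observed_count(ps.snp_indices, p, alpha)
        if ps.snp_indices.size:
            rotated_idx = (ps.snp_indices[None, :] - offsets[:, None]) % M
            counts = assoc[rotated_idx].sum(axis=1)
        else:
            counts = np.zeros(len(offsets), dtype=int)
        if strict:
            hits = int((counts > obs).sum())
        else:
            hits = int((counts >= obs).sum())
        results.append(
            PermutationResult(
                pathway_id=ps.pathway_id,
                n_genes=len(ps.genes),
                n_snps=int(ps.snp_indices.size),
                observed_count=obs,
                empirical_p=hits / len(offsets),
                perm_counts=counts if keep_perm_counts else None,
            )
        )
    return results


def pathway_bonferroni(n_pathways: int, n_analyses: int, fwer: float = 0.05) -> float:
    """Family-wise threshold over pathways x analyses."""
    if n_pathways < 1 or n_analyses < 1:
        raise ValueError("counts must be >= 1")
    return fwer / (n_pathways * n_analyses)


def results_table(
    results_by_analysis: dict[str, list[PermutationResult]]
) -> pd.DataFrame:
    """Tabulate permutation results, ranked within each analysis.

    Returns one row per (analysis, pathway) with the per-analysis rank of
    the empirical p (rank 1 = most significant), enabling rank comparison
    of a pathway across strata.
    """
    frames = []
    for tag, results in results_by_analysis.items():
        df = pd.DataFrame(
            {
                "analysis": tag,
                "pathway": [r.pathway_id for r in results],
                "n_genes": [r.n_genes for r in results],
                "n_snps": [r.n_snps for r in results],
                "observed_count": [r.observed_count for r in results],
                "empirical_p": [r.empirical_p for r in results],
            }
        )
        df["rank"] = df["empirical_p"].rank(method="min").astype(int)
        frames.append(df.sort_values(["empirical_p", "pathway"]).reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)
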