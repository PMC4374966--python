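"""Circular genomic permutation: annotation, counting, rotation oracles."""

import numpy as np
import pandas as pd
import pytest

import urategxe as u
from urategxe.pathways import (
    GenomeOrder,
    PathwaySet,
    read_gene_intervals,
    results_table,
    write_gmt,
)
from urategxe.simulate import _snp_metadata


def _genome(n=12):
    return GenomeOrder.from_metadata(_snp_metadata(n, np.full(n, 0.5), np.ones(n)))


# ---------------------------------------------------------------------------
# annotation


def test_snp_in_gene_interval_mapped():
    snps = pd.DataFrame({"snp": ["s1"], "chr": [1], "pos": [500]})
    genes = pd.DataFrame({"gene": ["G1"], "chr": [1], "start": [100], "end": [1000]})
    out = u.annotate_snps_to_genes(snps, genes)
    assert list(out["G1"]) == [0]


def test_snp_outside_gene_not_mapped():
    """No flanking window: a SNP 10 kb upstream stays unannotated."""
    snps = pd.DataFrame({"snp": ["s1"], "chr": [1], "pos": [90_000]})
    genes = pd.DataFrame({"gene": ["G1"], "chr": [1], "start": [100_000], "end": [150_000]})
    out = u.annotate_snps_to_genes(snps, genes)
    assert len(out["G1"]) == 0


def test_interval_boundaries_inclusive():
    snps = pd.DataFrame({"snp": ["a", "b", "c", "d"], "chr": 1, "pos": [99, 100, 200, 201]})
    genes = pd.DataFrame({"gene": ["G"], "chr": [1], "start": [100], "end": [200]})
    out = u.annotate_snps_to_genes(snps, genes)
    assert list(out["G"]) == [1, 2]


def test_overlapping_genes_both_annotated():
    snps = pd.DataFrame({"snp": ["s1"], "chr": [1], "pos": [500]})
    genes = pd.DataFrame(
        {"gene": ["A", "B"], "chr": [1, 1], "start": [100, 400], "end": [600, 900]}
    )
    out = u.annotate_snps_to_genes(snps, genes)
    assert list(out["A"]) == [0] and list(out["B"]) == [0]


def test_reversed_interval_rejected():
    snps = pd.DataFrame({"snp": ["s1"], "chr": [1], "pos": [500]})
    genes = pd.DataFrame({"gene": ["G1"], "chr": [1], "start": [900], "end": [100]})
    with pytest.raises(ValueError, match="start > end"):
        u.annotate_snps_to_genes(snps, genes)


def test_bed_dialect_converts_coordinates(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("chr1\t99\t200\tG1\n")  # 0-based half-open = 1-based 100..200
    df = read_gene_intervals(bed, dialect="bed")
    assert df.loc[0, "start"] == 100 and df.loc[0, "end"] == 200


def test_gmt_roundtrip(tmp_path):
    gmt = {"P1": ["G1", "G2"], "P2": ["G3"]}
    write_gmt(gmt, tmp_path / "sets.gmt")
    assert u.read_gmt(tmp_path / "sets.gmt") == gmt


# ---------------------------------------------------------------------------
# counting and permutation


def test_observed_count_boundary_and_enumeration():
    p = np.array([0.01, 0.2, 0.05, 0.9, 0.04, 0.5, 0.6, 0.7, 0.8, 0.051])
    idx = np.arange(10)
    assert u.observed_count(idx, p) == 3  # p = 0.05 exactly is counted
    assert u.observed_count(idx, np.ones(10)) == 0


def test_exhaustive_rotation_matches_brute_force_enumeration():
    """12-SNP toy circle: empirical p equals the exact ratio over 11 rotations."""
    genome = _genome(12)
    rng = np.random.default_rng(5)
    p = rng.uniform(size=12)
    idx = np.array([0, 3, 4, 7, 10])
    ps = PathwaySet("P1", ["g"], idx)
    res = u.circular_permutation_test([ps], p, genome, exhaustive=True, n_perm=10_000)[0]

    obs = (p[idx] <= 0.05).sum()
    brute = [
        (np.roll(p, d)[idx] <= 0.05).sum() for d in range(1, 12)
    ]
    assert res.empirical_p == pytest.approx(np.mean([c >= obs for c in brute]))
    assert res.observed_count == obs


def test_all_pvalues_one_gives_empirical_p_one():
    genome = _genome(20)
    ps = PathwaySet("P1", ["g"], np.array([1, 5, 9]))
    res = u.circular_permutation_test([ps], np.ones(20), genome, n_perm=50, seed=1)[0]
    assert res.observed_count == 0 and res.empirical_p == 1.0


def test_rotation_preserves_genomewide_association_count():
    rng = np.random.default_rng(9)
    p = rng.uniform(size=200)
    total = (p <= 0.05).sum()
    for d in (1, 17, 113):
        assert (np.roll(p, d) <= 0.05).sum() == total


def test_sampled_equals_exhaustive_when_nperm_reaches_all_rotations():
    genome = _genome(30)
    rng = np.random.default_rng(11)
    p = rng.uniform(size=30)
    ps = PathwaySet("P1", ["g"], np.array([2, 4, 8, 16]))
    a = u.circular_permutation_test([ps], p, genome, n_perm=29, seed=3)[0]
    b = u.circular_permutation_test([ps], p, genome, exhaustive=True, seed=4)[0]
    assert a.empirical_p == b.empirical_p


def test_empirical_p_on_grid_and_deterministic():
    genome = _genome(50)
    rng = np.random.default_rng(13)
    p = rng.uniform(size=50)
    ps = PathwaySet("P1", ["g"], np.array([3, 7, 21, 40]))
    r1 = u.circular_permutation_test([ps], p, genome, n_perm=40, seed=7)[0]
    r2 = u.circular_permutation_test([ps], p, genome, n_perm=40, seed=7)[0]
    assert r1.empirical_p == r2.empirical_p
    assert (r1.empirical_p * 40) == int(r1.empirical_p * 40)
    assert 0.0 <= r1.empirical_p <= 1.0


def test_strict_convention_never_exceeds_tie_convention():
    genome = _genome(40)
    rng = np.random.default_rng(17)
    p = rng.uniform(size=40)
    ps = PathwaySet("P1", ["g"], np.arange(0, 40, 5))
    tie = u.circular_permutation_test([ps], p, genome, exhaustive=True)[0]
    strict = u.circular_permutation_test([ps], p, genome, exhaustive=True, strict=True)[0]
    assert strict.empirical_p <= tie.empirical_p


@pytest.mark.parametrize(
    "n_path,n_ana,expect,sig",
    [(229, 9, 2.43e-5, 3), (1, 1, 0.05, 3), (17787, 1, 2.8e-6, 2)],
)
def test_pathway_bonferroni(n_path, n_ana, expect, sig):
    got = u.pathway_bonferroni(n_path, n_ana)
    assert float(f"{got:.{sig - 1}e}") == pytest.approx(expect, rel=1e-6)


def test_results_table_ranks_within_analysis():
    genome = _genome(60)
    rng = np.random.default_rng(19)
    p = rng.uniform(size=60)
    sets = [
        PathwaySet("P1", ["a"], np.arange(0, 10)),
        PathwaySet("P2", ["b"], np.arange(20, 35)),
    ]
    res = u.circular_permutation_test(sets, p, genome, n_perm=59, seed=2)
    tab = results_table({"lean": res, "obese": res})
    assert set(tab["analysis"]) == {"lean", "obese"}
    lean = tab[tab["analysis"] == "lean"]
    assert lean["rank"].min() == 1
    assert lean.sort_values("rank")["empirical_p"].is_monotonic_increasing
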