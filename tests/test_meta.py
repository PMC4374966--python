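"""Genomic control, IVW meta-analysis and the dominance/reporting filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import urategxe as u
from urategxe.meta import CHI2_MEDIAN_1DF


# ---------------------------------------------------------------------------
# genomic control


def test_lambda_is_one_at_the_chi_square_median():
    p = np.full(200, stats.chi2.sf(CHI2_MEDIAN_1DF, df=1))
    assert u.genomic_lambda(p).lam == pytest.approx(1.0, abs=1e-12)


def test_lambda_calibrated_on_uniform_pvalues():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=100_000)
    assert 0.98 <= u.genomic_lambda(p).lam <= 1.02


def test_lambda_warns_below_100_pvalues():
    with pytest.warns(UserWarning, match="unstable"):
        u.genomic_lambda(np.random.default_rng(0).uniform(size=50))


def test_gc_correct_scales_se_and_recomputes_p():
    rec = pd.DataFrame({"beta": [0.2], "se": [0.1], "p": [0.0455]})  # z = 2
    out = u.gc_correct(rec, 1.21)
    z = 2 / 1.1
    assert out["se"].iloc[0] == pytest.approx(0.11, abs=1e-12)
    assert out["beta"].iloc[0] == 0.2  # betas untouched
    assert out["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(z), abs=1e-6)
    assert out["p"].iloc[0] == pytest.approx(0.0690, abs=5e-4)


@pytest.mark.parametrize("lam", [1.0, 0.95, 0.5])
def test_gc_correct_identity_when_lambda_not_above_one(lam):
    rec = pd.DataFrame({"beta": [0.2], "se": [0.1], "p": [0.0455]})
    pd.testing.assert_frame_equal(u.gc_correct(rec, lam), rec)


# ---------------------------------------------------------------------------
# IVW pooling


def test_ivw_reproduces_published_combined_interaction_estimate():
    """Pooling the discovery and replication interaction rows for RBFOX3."""
    from urategxe.datasets import RBFOX3_INTERACTION

    res = u.meta_record(RBFOX3_INTERACTION["beta"], RBFOX3_INTERACTION["se"])
    assert round(res["beta"], 3) == -0.014


def test_ivw_two_identical_studies():
    res = u.meta_record([0.3, 0.3], [0.1, 0.1])
    assert res["beta"] == pytest.approx(0.3)
    assert res["se"] == pytest.approx(0.1 / np.sqrt(2))
    assert res["Q"] == pytest.approx(0.0, abs=1e-12)
    assert res["max_contribution"] == pytest.approx(0.5)


def test_ivw_hand_computed_example():
    res = u.meta_record([1.0, 0.0], [1.0, 1.0])
    assert res["beta"] == pytest.approx(0.5)
    assert res["se"] == pytest.approx(0.70711, abs=1e-5)
    assert res["Q"] == pytest.approx(0.5)
    assert res["I2"] == pytest.approx(0.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.floats(-2, 2), st.floats(0.01, 3)), min_size=1, max_size=8
    )
)
def test_ivw_equals_weighted_least_squares_oracle(data):
    """IVW pooling is WLS of betas on an intercept with weights 1/SE^2."""
    import statsmodels.api as sm

    betas = np.array([d[0] for d in data])
    ses = np.array([d[1] for d in data])
    res = u.meta_record(betas, ses)
    wls = sm.WLS(betas, np.ones_like(betas), weights=1.0 / ses**2).fit()
    assert res["beta"] == pytest.approx(float(wls.params[0]), abs=1e-12)
    # WLS oracle SE: sqrt(1/sum w) equals the unscaled covariance
    assert res["se"] == pytest.approx(float(np.sqrt(1.0 / np.sum(ses**-2))), abs=1e-12)


def test_ivw_study_order_invariance():
    betas, ses = [0.1, -0.2, 0.05], [0.02, 0.07, 0.4]
    a = u.meta_record(betas, ses)
    b = u.meta_record(betas[::-1], ses[::-1])
    for k in ("beta", "se", "p", "Q", "I2", "max_contribution"):
        assert a[k] == pytest.approx(b[k], abs=1e-14)


def test_infinite_se_study_changes_nothing():
    a = u.meta_record([0.1, -0.2], [0.02, 0.07])
    b = u.meta_record([0.1, -0.2, 5.0], [0.02, 0.07, np.inf])
    for k in ("beta", "se", "Q"):
        assert a[k] == pytest.approx(b[k], abs=1e-14)


def test_contributions_sum_to_one_and_i2_bounds():
    rng = np.random.default_rng(3)
    res = u.ivw_combine(rng.normal(size=(6, 40)), rng.uniform(0.01, 1, size=(6, 40)))
    np.testing.assert_allclose(res["contributions"].sum(axis=0), 1.0, atol=1e-10)
    assert np.all((res["I2"] >= 0) & (res["I2"] <= 100))
    assert np.all(res["Q"] >= -1e-12)


# ---------------------------------------------------------------------------
# allele alignment


def test_allele_swap_flips_beta_sign():
    ref = pd.DataFrame({"snp": ["s1"], "A1": ["A"], "A2": ["G"], "freqA1": [0.3]})
    rec = pd.DataFrame(
        {"snp": ["s1"], "A1": ["G"], "A2": ["A"], "freqA1": [0.7],
         "beta": [0.5], "se": [0.1]}
    )
    out, log = u.align_alleles(rec, ref)
    assert out["beta"].iloc[0] == -0.5
    assert out["freqA1"].iloc[0] == pytest.approx(0.3)
    assert log["flipped"] == 1


def test_ambiguous_snp_dropped_at_high_maf_aligned_at_low_maf():
    ref = pd.DataFrame(
        {"snp": ["s1", "s2"], "A1": ["A", "A"], "A2": ["T", "T"], "freqA1": [0.45, 0.1]}
    )
    rec = pd.DataFrame(
        {"snp": ["s1", "s2"], "A1": ["A", "T"], "A2": ["T", "A"],
         "freqA1": [0.45, 0.9], "beta": [0.2, 0.3], "se": [0.1, 0.1]}
    )
    out, log = u.align_alleles(rec, ref)
    assert "s1" not in set(out["snp"])          # maf 0.45 >= 0.4: dropped
    assert out.loc[out["snp"] == "s2", "beta"].iloc[0] == -0.3  # freq-aligned flip


def test_allele_mismatch_dropped_and_logged():
    ref = pd.DataFrame({"snp": ["s1"], "A1": ["A"], "A2": ["G"], "freqA1": [0.3]})
    rec = pd.DataFrame(
        {"snp": ["s1"], "A1": ["A"], "A2": ["C"], "freqA1": [0.3],
         "beta": [0.5], "se": [0.1]}
    )
    out, log = u.align_alleles(rec, ref)
    assert len(out) == 0 and log["dropped_mismatch"] == 1


# ---------------------------------------------------------------------------
# filters


@pytest.mark.parametrize(
    "max_contrib,threshold,kept",
    [(0.5, 0.5, True), (0.501, 0.5, False), (1.0, 0.99, False), (0.32, 0.30, False)],
)
def test_contribution_filter_strict(max_contrib, threshold, kept):
    assert u.contribution_filter(max_contrib, threshold) is kept


@pytest.mark.parametrize(
    "maf,k,mc,kept",
    [
        (0.03, 3, 0.2, False),   # too few studies
        (0.03, 5, 0.25, True),
        (0.03, 5, 0.32, False),  # one study dominates
        (0.03, 4, 0.30, True),   # boundaries inclusive
        (0.10, 1, 1.0, True),    # rule not applied at maf >= 5%
    ],
)
def test_low_maf_rule(maf, k, mc, kept):
    assert u.low_maf_rule(maf, k, mc) is kept


def test_meta_of_null_consortium_lambda(small_consortium, small_adjusted):
    _, cohorts, _ = small_consortium
    recs = pd.concat(
        [u.run_stratum_gwas(c, small_adjusted[c.cohort_id], "overweight") for c in cohorts],
        ignore_index=True,
    )
    meta = u.ivw_meta(recs, reference=cohorts[0].snps)
    lam = u.genomic_lambda(meta["p"].dropna().to_numpy())
    assert 0.85 <= lam.lam <= 1.15  # 300 SNPs only; the 5000-SNP check is in acceptance
    assert meta["n_studies"].max() == 3
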