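"""Interaction regression vs explicit matrix oracles; centering; MAF cut."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import urategxe as u
from urategxe.interaction import interaction_fit

from conftest import toy_cohort


@pytest.fixture(scope="module")
def toy12():
    """12-row fixed dataset with heteroskedastic-looking spread."""
    g = np.array([0, 0, 0, 1, 1, 1, 1, 1, 2, 2, 2, 2], dtype=float)
    bmi = np.array([21.0, 24.5, 31.0, 19.8, 23.0, 27.5, 29.0, 33.1, 22.2, 26.0, 30.5, 35.0])
    y = np.array([-0.8, -0.2, 0.4, -1.1, 0.1, 0.3, 0.9, 1.4, -0.5, 0.2, 0.8, 1.9])
    return y, bmi, g


def _oracle(y, bmi, g):
    X = np.column_stack([np.ones_like(y), bmi, g, bmi * g])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    e = y - X @ beta
    sigma2 = e @ e / (len(y) - 4)
    cov_classical = sigma2 * xtx_inv
    meat = X.T @ np.diag(e**2) @ X
    cov_hc0 = xtx_inv @ meat @ xtx_inv
    return beta, np.sqrt(cov_classical[3, 3]), np.sqrt(cov_hc0[3, 3])


def test_classical_fit_matches_matrix_oracle(toy12):
    y, bmi, g = toy12
    beta_o, se_o, _ = _oracle(y, bmi, g)
    fit = interaction_fit(y, bmi, g[:, None], robust=False)
    for i, key in enumerate(["beta0", "beta1", "beta2", "beta12"]):
        assert fit[key][0] == pytest.approx(beta_o[i], abs=1e-10)
    assert fit["se12"][0] == pytest.approx(se_o, abs=1e-10)


def test_hc0_sandwich_matches_matrix_oracle(toy12):
    y, bmi, g = toy12
    _, _, se_hc0 = _oracle(y, bmi, g)
    fit = interaction_fit(y, bmi, g[:, None], robust=True)
    assert fit["se12"][0] == pytest.approx(se_hc0, abs=1e-10)


def test_p_values_consistent_with_reference_distributions(toy12):
    y, bmi, g = toy12
    classical = interaction_fit(y, bmi, g[:, None], robust=False)
    robust = interaction_fit(y, bmi, g[:, None], robust=True)
    t = classical["beta12"][0] / classical["se12"][0]
    assert classical["p12"][0] == pytest.approx(2 * stats.t.sf(abs(t), df=8), abs=1e-6)
    z = robust["beta12"][0] / robust["se12"][0]
    assert robust["p12"][0] == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-6)


def test_vectorised_fit_agrees_with_per_snp_oracle():
    rng = np.random.default_rng(4)
    n, m = 150, 12
    G = rng.binomial(2, 0.4, size=(n, m)).astype(float)
    bmi = rng.normal(26, 4, n)
    y = rng.normal(size=n)
    fit = interaction_fit(y, bmi, G, robust=True)
    for j in range(m):
        _, _, se_hc0 = _oracle(y, bmi, G[:, j])
        beta_o, se_cl, _ = _oracle(y, bmi, G[:, j])
        assert fit["beta12"][j] == pytest.approx(beta_o[3], abs=1e-9)
        assert fit["se12"][j] == pytest.approx(se_hc0, abs=1e-9)


def test_centering_shifts_beta2_exactly(toy12):
    """BMI -> BMI - c changes beta2 by c*beta12, leaves beta12 and se12 alone."""
    y, bmi, g = toy12
    plain = interaction_fit(y, bmi, g[:, None], robust=False)
    centred = interaction_fit(y, bmi, g[:, None], robust=False, center_bmi=True)
    assert centred["beta12"][0] == pytest.approx(plain["beta12"][0], abs=1e-8)
    assert centred["se12"][0] == pytest.approx(plain["se12"][0], abs=1e-8)
    # mapped-back coefficients reproduce the uncentered parameterisation
    assert centred["beta2"][0] == pytest.approx(plain["beta2"][0], abs=1e-8)
    shifted = interaction_fit(y, bmi - 3.0, g[:, None], robust=False)
    assert shifted["beta2"][0] - plain["beta2"][0] == pytest.approx(
        3.0 * plain["beta12"][0], abs=1e-8
    )


def test_robust_and_classical_converge_under_homoskedasticity():
    rng = np.random.default_rng(8)
    n = 10_000
    g = rng.binomial(2, 0.5, n).astype(float)
    bmi = rng.normal(26, 4.5, n)
    y = 0.01 * bmi * g + rng.normal(size=n)
    cl = interaction_fit(y, bmi, g[:, None], robust=False)
    ro = interaction_fit(y, bmi, g[:, None], robust=True)
    assert 0.9 <= ro["se12"][0] / cl["se12"][0] <= 1.1


def test_robust_branch_deflates_heteroskedastic_null_lambda():
    """Noise scaled by BMI inflates the classical interaction lambda more."""
    rng = np.random.default_rng(15)
    n, m = 4000, 400
    G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    bmi = rng.normal(26, 4.5, n)
    y = rng.normal(size=n) * (bmi / 26.0)  # SD proportional to BMI, beta12 = 0
    cl = interaction_fit(y, bmi, G, robust=False)
    ro = interaction_fit(y, bmi, G, robust=True)
    lam_cl = u.genomic_lambda(cl["p12"]).lam
    lam_ro = u.genomic_lambda(ro["p12"]).lam
    assert abs(lam_ro - 1.0) < abs(lam_cl - 1.0)


def test_null_interaction_type_one_error():
    rng = np.random.default_rng(23)
    n, m = 2500, 2000
    G = rng.binomial(2, 0.4, size=(n, m)).astype(float)
    bmi = rng.normal(26, 4.5, n)
    y = rng.normal(size=n)
    fit = interaction_fit(y, bmi, G, robust=False)
    assert 0.03 <= (fit["p12"] < 0.05).mean() <= 0.07


def test_constant_dosage_flagged_unusable():
    y = np.random.default_rng(0).normal(size=60)
    bmi = np.random.default_rng(1).normal(26, 4, 60)
    G = np.column_stack([np.ones(60), np.random.default_rng(2).binomial(2, 0.5, 60)])
    fit = interaction_fit(y, bmi, G.astype(float))
    assert not fit["usable"][0] and fit["usable"][1]
    assert np.isnan(fit["beta12"][0])


def test_run_interaction_gwas_robust_withholds_main_effects(small_consortium, small_adjusted):
    _, cohorts, _ = small_consortium
    rec = u.run_interaction_gwas(cohorts[0], small_adjusted["cohort1"], robust=True)
    assert rec["beta1"].isna().all() and rec["beta2"].isna().all()
    assert rec["beta12"].notna().all()
    classical = u.run_interaction_gwas(cohorts[0], small_adjusted["cohort1"], robust=False)
    assert classical["beta1"].notna().all()
    # the point estimate is identical across branches
    np.testing.assert_allclose(rec["beta12"], classical["beta12"], atol=1e-12)


def test_interaction_maf_filter_boundary():
    rec = pd.DataFrame({"snp": ["a", "b", "c"], "freqA1": [0.04, 0.05, 0.30]})
    kept = u.interaction_maf_filter(rec, 0.05)
    assert list(kept["snp"]) == ["b", "c"]


def test_interaction_beta12_recovered_at_scale():
    """Generated beta12 = 0.01 per BMI unit is recovered within 2 combined SE.

    Six independent effect SNPs at n=50k are IVW-combined. z-scoring the
    residualized trait attenuates coefficients by the residual SD of the
    latent trait, so the expectation is compared on the generating scale
    using the scale estimated from the residualization regression.
    """
    m = 6
    cfg = u.SimulationConfig(
        n_cohorts=1, n_per_cohort=50_000, n_snps=m, seed=31,
        interaction_effects=np.full(m, 0.01),
    )
    rng = np.random.default_rng(31)
    dos, snps = u.simulate_genotypes(50_000, m, freqs=np.full(m, 0.5), rng=rng)
    table, _ = u.simulate_phenotypes(dos, snps, cfg, rng=rng)
    adj = u.residualize(table, ["age", "sex", "pc1", "pc2"])
    rec = u.run_interaction_gwas(table, adj)

    ph = table.phenotypes
    X = np.column_stack([
        np.ones(len(ph)), ph["age"], (ph["sex"] == "M").astype(float),
        ph["pc1"], ph["pc2"],
    ])
    y = ph["urate"].to_numpy()
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    scale = (y - X @ coef).std(ddof=1) / 1.3  # latent-trait residual SD

    pooled = u.meta_record(rec["beta12"], rec["se12"])
    assert abs(pooled["beta"] * scale - 0.01) < 2 * pooled["se"] * scale
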