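import numpy as np
import pandas as pd
import pytest

import urategxe as u
from urategxe.residualize import AdjustedTrait
from urategxe.simulate import CohortTable, _snp_metadata


@pytest.fixture(scope="session")
def small_consortium():
    """Three null cohorts sharing one SNP panel; enough rows per stratum."""
    cfg = u.SimulationConfig(n_cohorts=3, n_per_cohort=600, n_snps=300, seed=11)
    cohorts, truth = u.simulate_consortium(cfg)
    return cfg, cohorts, truth


@pytest.fixture(scope="session")
def small_adjusted(small_consortium):
    _, cohorts, _ = small_consortium
    return {c.cohort_id: u.residualize(c, ["age", "sex", "pc1", "pc2"]) for c in cohorts}


def toy_cohort(dosages: np.ndarray, trait: np.ndarray, bmi: np.ndarray) -> tuple[CohortTable, AdjustedTrait]:
    """Wrap raw vectors into the containers the association ops consume.

    The adjusted trait is passed through verbatim (not re-standardised) so
    closed-form oracles apply to the exact numbers given.
    """
    dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
    if dosages.shape[0] == 1:
        dosages = dosages.T
    n, m = dosages.shape
    pheno = pd.DataFrame(
        {
            "id": [f"t{i}" for i in range(n)],
            "age": 50.0,
            "sex": "F",
            "bmi": np.asarray(bmi, dtype=float),
            "urate": np.asarray(trait, dtype=float),
        }
    )
    snps = _snp_metadata(m, np.full(m, 0.5), np.ones(m))
    cohort = CohortTable("toy", pheno, dosages, snps)
    adjusted = AdjustedTrait(
        "toy", pd.Series(np.asarray(trait, dtype=float), index=pheno["id"].to_numpy())
    )
    return cohort, adjusted
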