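"""Trait residualization: urate adjusted for covariates, z-scored per cohort.

The analysis trait is the residual of serum urate on age, sex (in
combined-sex analyses) and ancestry principal components, standardised to
mean 0 / SD 1 within the analysed subset. Missing covariate or trait rows
are dropped listwise before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .simulate import CohortTable


@dataclass
class AdjustedTrait:
    """Per-individual residual z-scores with provenance."""

    cohort_id: str
    values: pd.Series  # indexed by individual id
    covariates_used: list[str] = field(default_factory=list)
    sex_combined: bool = True

    def __len__(self) -> int:
        return len(self.values)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name columns responsible for rank deficiency via pivoted QR."""
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = piv[np.flatnonzero(diag < tol)]
    # rank deficiency also hides columns beyond the R diagonal
    rank = int((diag >= tol).sum())
    bad = sorted(set(bad.tolist()) | set(piv[rank:].tolist()))
    return [names[i] for i in bad if names[i] != "intercept"]


def residualize(
    cohort: CohortTable | pd.DataFrame,
    covariates: list[str],
    sex_combined: bool = True,
    trait: str = "urate",
) -> AdjustedTrait:
    """Least-squares adjust ``trait`` for ``covariates`` and z-score.

    ``sex`` is included as a covariate only when ``sex_combined`` is true
    (sex-stratified analyses fit within one sex, where sex is constant).
    The z-score uses the n-1 sample standard deviation. Raises ``ValueError``
    on a rank-deficient design (naming the collinear columns), on an
    all-missing trait, or on fewer than 10 complete rows.
    """
    df = cohort.phenotypes if isinstance(cohort, CohortTable) else cohort
    cohort_id = cohort.cohort_id if isinstance(cohort, CohortTable) else "cohort"

    covs = [c for c in covariates if c != "sex" or sex_combined]
    missing = [c for c in covs if c not in df.columns]
    if missing:
        raise ValueError(f"covariates not found in cohort table: {missing}")
    if trait not in df.columns:
        raise ValueError(f"trait column {trait!r} not found")
    if df[trait].notna().sum() == 0:
        raise ValueError("trait is entirely missing")

    work = df[["id", trait, *covs]].dropna()
    if len(work) < 10:
        raise ValueError(
            f"only {len(work)} complete rows; need at least 10 to residualize"
        )

    y = work[trait].to_numpy(dtype=float)
    cols = [np.ones(len(work))]
    names = ["intercept"]
    for c in covs:
        v = work[c]
        if v.dtype == object or str(v.dtype) == "category":
            # binary encoding for sex-like factors
            levels = sorted(v.unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {c!r} has >2 categorical levels")
            cols.append((v == levels[-1]).to_numpy(dtype=float))
        else:
            cols.append(v.to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)

    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {bad}")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    z = (resid - resid.mean()) / resid.std(ddof=1)
    return AdjustedTrait(
        cohort_id=cohort_id,
        values=pd.Series(z, index=work["id"].to_numpy(), name="z_resid"),
        covariates_used=covs,
        sex_combined=sex_combined,
    )
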