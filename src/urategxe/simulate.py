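"""Synthetic multi-cohort genotype/phenotype generator.

Emulates the statistical structure of a consortium of unrelated
European-ancestry-like population cohorts with measured serum urate and BMI:
hard-call (or fractional) SNP dosages in Hardy-Weinberg proportions, BMI
distributions spanning the lean/overweight/obese range, covariate effects
(age, sex, ancestry principal components acting as mild confounders) and
optional per-SNP main and SNP-by-BMI interaction effects on the trait.

The generative trait model is the one the downstream interaction regression
fits, inverted::

    trait = a*age + s*male + sum_k c_k*PC_k + b*BMI
            + sum_j (beta_j + beta12_j * BMI) * dose_j + eps,   eps ~ N(0, noise_sd)

so a fitted interaction coefficient estimates ``beta12_j`` (per allele per
kg/m^2 on the z-scored trait). Genotypes are independent across SNPs: the
generator provides genome ordering for circular permutation, not realistic LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

N_CHROMOSOMES = 22
#: nominal per-chromosome length (bp) used to spread synthetic SNP positions
CHROM_LENGTH = 100_000_000

# covariate effects on the latent z-scale trait; chosen so that
# residualization on age/sex/PCs is non-trivial but the residual SD stays
# close to noise_sd
AGE_EFFECT = 0.01       # per year, centred at 50 y
SEX_EFFECT = 0.8        # male minus female, mimics higher urate in men
PC_EFFECT = 0.1         # per PC unit
BMI_MAIN_EFFECT = 0.03  # per kg/m^2, mimics the positive BMI-urate gradient
PC_BMI_LOADING = 0.03   # PCs correlate mildly with BMI (confounding)
URATE_MEAN = 4.5        # mg/dl offset when mapping the z-scale trait
URATE_SCALE = 1.3       # mg/dl per z unit


@dataclass
class SimulationConfig:
    """Parameters of one synthetic consortium.

    ``n_per_cohort`` may be a single count (shared by all cohorts) or one
    count per cohort. Effect vectors default to all-null.
    """

    n_cohorts: int = 5
    n_per_cohort: int | Sequence[int] = 2000
    n_snps: int = 2000
    freq_range: tuple[float, float] = (0.05, 0.95)
    main_effects: np.ndarray | None = None
    interaction_effects: np.ndarray | None = None
    bmi_mean_by_sex: dict[str, float] = field(
        default_factory=lambda: {"M": 27.5, "F": 26.0}
    )
    bmi_sd: float = 4.5
    age_range: tuple[float, float] = (30.0, 75.0)
    sex_fraction: float = 0.5
    n_pcs: int = 2
    noise_sd: float = 1.0
    fractional_dosage: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be positive")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        lo, hi = self.freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"freq_range must lie strictly inside (0,1), got {self.freq_range}")
        if self.bmi_sd <= 0:
            raise ValueError("bmi_sd must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.sex_fraction <= 1.0:
            raise ValueError("sex_fraction must be in [0,1]")
        for name in ("main_effects", "interaction_effects"):
            vec = getattr(self, name)
            if vec is not None:
                vec = np.asarray(vec, dtype=float)
                if vec.shape != (self.n_snps,):
                    raise ValueError(
                        f"{name} has length {vec.shape}, expected ({self.n_snps},)"
                    )
                setattr(self, name, vec)

    @property
    def cohort_sizes(self) -> list[int]:
        if np.isscalar(self.n_per_cohort):
            return [int(self.n_per_cohort)] * self.n_cohorts
        sizes = [int(n) for n in self.n_per_cohort]
        if len(sizes) != self.n_cohorts:
            raise ValueError("n_per_cohort length must equal n_cohorts")
        return sizes


@dataclass
class CohortTable:
    """One cohort: phenotypes/covariates, dosages and SNP metadata.

    ``phenotypes`` rows are individuals (columns: id, age, sex, bmi, urate,
    pc1..pcK); ``dosages`` is individuals x SNPs in [0, 2]; ``snps`` carries
    (snp, chr, pos, A1, A2, freqA1, info).
    """

    cohort_id: str
    phenotypes: pd.DataFrame
    dosages: np.ndarray
    snps: pd.DataFrame
    dialect: str = "mach"  # imputation-quality dialect: "mach" or "impute"

    @property
    def n(self) -> int:
        return len(self.phenotypes)


def _snp_metadata(n_snps: int, freqs: np.ndarray, info: np.ndarray) -> pd.DataFrame:
    """Lay SNPs out in genome order over chromosomes 1..22, evenly spaced."""
    per_chrom = np.full(N_CHROMOSOMES, n_snps // N_CHROMOSOMES)
    per_chrom[: n_snps % N_CHROMOSOMES] += 1
    chroms = np.repeat(np.arange(1, N_CHROMOSOMES + 1), per_chrom)
    pos = np.concatenate(
        [
            np.linspace(1, CHROM_LENGTH, k, dtype=np.int64)
            for k in per_chrom
            if k > 0
        ]
    )
    # alternating allele labels; never strand-ambiguous so meta alignment is exact
    a1 = np.where(np.arange(n_snps) % 2 == 0, "A", "G")
    a2 = np.where(np.arange(n_snps) % 2 == 0, "G", "A")
    return pd.DataFrame(
        {
            "snp": [f"rs{i + 1:06d}" for i in range(n_snps)],
            "chr": chroms.astype(int),
            "pos": pos,
            "A1": a1,
            "A2": a2,
            "freqA1": freqs,
            "info": info,
        }
    )


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    freq_range: tuple[float, float] = (0.05, 0.95),
    seed: int | None = None,
    freqs: np.ndarray | None = None,
    fractional: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw a dosage matrix plus SNP metadata.

    Allele frequencies are Uniform(freq_range) unless ``freqs`` is given;
    genotypes are Binomial(2, f) hard calls. With ``fractional=True`` each
    SNP's hard calls are shrunk toward the frequency mean ``2f`` by a random
    per-SNP weight, mimicking imputed doses, and the ``info`` column records
    the resulting variance ratio; hard calls carry info = 1.
    """
    if n_individuals < 1 or n_snps < 1:
        raise ValueError("n_individuals and n_snps must be >= 1")
    lo, hi = freq_range
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"freq_range must lie strictly inside (0,1), got {freq_range}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if freqs is None:
        freqs = rng.uniform(lo, hi, size=n_snps)
    else:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (n_snps,):
            raise ValueError("freqs length must equal n_snps")
    dosages = rng.binomial(2, freqs, size=(n_individuals, n_snps)).astype(float)
    if fractional:
        w = rng.uniform(0.0, 0.4, size=n_snps)  # shrinkage toward 2f
        dosages = (1.0 - w) * dosages + w * (2.0 * freqs)
        info = (1.0 - w) ** 2  # var ratio vs perfectly observed genotype
    else:
        info = np.ones(n_snps)
    return dosages, _snp_metadata(n_snps, freqs, info)


def simulate_phenotypes(
    dosages: np.ndarray,
    snps: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    cohort_id: str = "cohort1",
    bmi_shift: float = 0.0,
) -> tuple[CohortTable, pd.DataFrame]:
    """Generate covariates and the urate-like trait for given genotypes.

    Returns the assembled :class:`CohortTable` and the truth table of
    generating per-SNP parameters (freqA1, beta_main, beta_inter).
    """
    n, m = dosages.shape
    if m != config.n_snps:
        raise ValueError("dosage matrix does not match config.n_snps")
    beta = (
        np.zeros(m) if config.main_effects is None else config.main_effects
    )
    beta12 = (
        np.zeros(m)
        if config.interaction_effects is None
        else config.interaction_effects
    )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    male = rng.random(n) < config.sex_fraction
    sex = np.where(male, "M", "F")
    age = rng.uniform(*config.age_range, size=n)
    bmi_mean = np.where(
        male, config.bmi_mean_by_sex["M"], config.bmi_mean_by_sex["F"]
    )
    bmi = rng.normal(bmi_mean + bmi_shift, config.bmi_sd, size=n)
    bmi = np.clip(bmi, 15.0, None)  # kg/m^2; no implausible underweight tail
    pcs = rng.normal(size=(n, config.n_pcs)) + PC_BMI_LOADING * (
        bmi[:, None] - bmi_mean[:, None]
    )

    genetic = dosages @ beta + (dosages * bmi[:, None]) @ beta12
    trait_z = (
        AGE_EFFECT * (age - 50.0)
        + SEX_EFFECT * male
        + PC_EFFECT * pcs.sum(axis=1)
        + BMI_MAIN_EFFECT * (bmi - 26.0)
        + genetic
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    urate = URATE_MEAN + URATE_SCALE * trait_z

    pheno = pd.DataFrame(
        {
            "id": [f"{cohort_id}_{i + 1:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "urate": urate,
        }
    )
    for k in range(config.n_pcs):
        pheno[f"pc{k + 1}"] = pcs[:, k]

    truth = pd.DataFrame(
        {
            "snp": snps["snp"].to_numpy(),
            "freqA1": snps["freqA1"].to_numpy(),
            "beta_main": beta,
            "beta_inter": beta12,
        }
    )
    table = CohortTable(cohort_id, pheno, dosages, snps.copy())
    return table, truth


def simulate_consortium(
    config: SimulationConfig,
) -> tuple[list[CohortTable], pd.DataFrame]:
    """Generate ``n_cohorts`` cohorts sharing one SNP panel and truth table.

    A master RNG (from ``config.seed``) fixes the shared allele frequencies
    and per-cohort BMI shifts; cohort ``i`` then uses seed ``seed + i + 1``,
    so the consortium is bitwise reproducible and cohorts are independent.
    """
    if config.n_cohorts < 2:
        raise ValueError("a consortium needs n_cohorts >= 2")
    master = np.random.default_rng(config.seed)
    lo, hi = config.freq_range
    freqs = master.uniform(lo, hi, size=config.n_snps)
    bmi_shifts = master.uniform(-1.5, 1.5, size=config.n_cohorts)
    dialects = ["mach", "impute"]

    cohorts: list[CohortTable] = []
    truth: pd.DataFrame | None = None
    for i, n_i in enumerate(config.cohort_sizes):
        rng = np.random.default_rng(config.seed + i + 1)
        dos, snps = simulate_genotypes(
            n_i,
            config.n_snps,
            config.freq_range,
            freqs=freqs,
            fractional=config.fractional_dosage,
            rng=rng,
        )
        table, truth = simulate_phenotypes(
            dos,
            snps,
            config,
            rng=rng,
            cohort_id=f"cohort{i + 1}",
            bmi_shift=float(bmi_shifts[i]),
        )
        table.dialect = dialects[i % 2]
        cohorts.append(table)
    assert truth is not None
    return cohorts, truth


# ---------------------------------------------------------------------------
# gene / pathway annotation fixtures for the permutation stage


def simulate_gene_annotation(
    snps: pd.DataFrame,
    n_genes: int = 200,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tile synthetic gene intervals (1-based, inclusive) over the SNP map.

    Genes are centred on randomly chosen SNPs so that most genes contain at
    least one SNP; interval half-width is drawn uniformly so gene SNP counts
    vary. Returns columns (gene, chr, start, end).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    m = len(snps)
    centres = rng.choice(m, size=n_genes, replace=True)
    half = rng.integers(1, CHROM_LENGTH // 40, size=n_genes)
    rows = []
    for g, (c, h) in enumerate(zip(centres, half)):
        chrom = int(snps["chr"].iloc[c])
        pos = int(snps["pos"].iloc[c])
        rows.append(
            {
                "gene": f"GENE{g + 1:04d}",
                "chr": chrom,
                "start": max(1, pos - int(h)),
                "end": pos + int(h),
            }
        )
    return pd.DataFrame(rows)


def simulate_pathways(
    genes: Sequence[str],
    n_pathways: int = 20,
    size_range: tuple[int, int] = (5, 40),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict[str, list[str]]:
    """Draw random gene sets (GMT-style mapping pathway -> member genes)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    genes = list(genes)
    lo, hi = size_range
    hi = min(hi, len(genes))
    out: dict[str, list[str]] = {}
    for p in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        out[f"PATH{p + 1:04d}"] = [genes[i] for i in sorted(members)]
    return out


# ---------------------------------------------------------------------------
# plain-text writers (fixed interchange columns)


def write_cohort(cohort: CohortTable, outdir: str | Path) -> None:
    """Write one cohort as phenotype/dosage/SNP-metadata TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.phenotypes.to_csv(
        outdir / f"{cohort.cohort_id}.pheno.tsv", sep="\t", index=False, na_rep="NA"
    )
    dosage = pd.DataFrame(
        cohort.dosages, columns=cohort.snps["snp"], index=cohort.phenotypes["id"]
    )
    dosage.to_csv(outdir / f"{cohort.cohort_id}.dosage.tsv", sep="\t", na_rep="NA")
    cohort.snps.to_csv(
        outdir / f"{cohort.cohort_id}.snps.tsv", sep="\t", index=False, na_rep="NA"
    )


def read_cohort(outdir: str | Path, cohort_id: str, dialect: str = "mach") -> CohortTable:
    outdir = Path(outdir)
    pheno = pd.read_csv(outdir / f"{cohort_id}.pheno.tsv", sep="\t")
    dosage = pd.read_csv(outdir / f"{cohort_id}.dosage.tsv", sep="\t", index_col=0)
    snps = pd.read_csv(outdir / f"{cohort_id}.snps.tsv", sep="\t")
    return CohortTable(cohort_id, pheno, dosage.to_numpy(dtype=float), snps, dialect)
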