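# Methods

This note documents the statistical procedures implemented in `urategxe`,
the synthetic data they are exercised on, and the numerical and design
choices made where conventions differ in the field.

## The analysis trait

Serum urate (mg/dl) is adjusted per cohort for age, sex and ancestry
principal components by ordinary least squares, and the residuals are
z-scored with the n−1 sample standard deviation. Sex enters the covariate
set only in combined-sex analyses; in sex-stratified runs it is constant
and is dropped. Missing trait or covariate rows are removed listwise
before fitting; a rank-deficient covariate matrix is an error that names
the collinear columns. Residualization happens once per cohort, before BMI
stratification, and residuals are not re-standardised within strata.
Medication use is not modelled.

Consequence worth keeping in mind: z-scoring divides every downstream
regression coefficient by the residual SD of the trait, which includes the
genetic variance itself. With realistic effect sizes this attenuation is
1–4%, well inside sampling noise at desk scale; the recovery tests
account for it explicitly where they average over many SNPs.

## Stratified association and QC

BMI strata are lean (BMI < 25), overweight (25 ≤ BMI ≤ 30, both boundaries
inclusive) and obese (BMI > 30 kg/m²); every individual with a positive,
finite BMI falls in exactly one stratum. Within a (cohort × stratum) cell
the z-residual is regressed on allele dose with an intercept; p-values use
the t distribution with n−2 df (indistinguishable from the normal at GWAS
sample sizes, exact at small n). Cells with fewer than 30 individuals are
skipped — the cut-off is an artifact choice to avoid degenerate fits, not
a published value. The effect-allele frequency is the dosage mean / 2 in
the analysed subset.

QC drops records with MAF < 1%, imputation quality below the dialect
threshold (r2hat < 0.3 for MACH-style cohorts, info < 0.4 for
IMPUTE-style), or a failed fit (zero dosage variance). All thresholds are
"less than" exclusions, so boundary values are retained. Exclusion counts
are logged per reason and reconcile with the input count.

## Genomic control and meta-analysis

λ is the median of the 1-df chi-square statistics implied by the two-sided
p-values, divided by the chi-square(1) median (≈ 0.45494). Correction is
applied per study when λ > 1 by scaling SEs by √λ and recomputing p from
the corrected z (normal); λ ≤ 1 is never applied (no deflation), and
pooled results are not corrected a second time. Scaling SEs rather than
dividing chi-squares keeps betas untouched and is equivalent for z-based
p-values.

Pooling is fixed-effects inverse-variance: w = 1/SE², β̂ = Σwβ/Σw,
SE = 1/√Σw, two-sided normal p, Q = Σw(β−β̂)², I² = max(0, (Q−(k−1))/Q)·100.
Studies are first oriented to reference alleles: an A1/A2 swap flips the
beta sign and frequency; strand flips resolve through complements;
strand-ambiguous SNPs (A/T, C/G) are aligned by frequency when MAF < 0.4
and dropped otherwise. A study with infinite SE carries zero weight and
changes nothing.

Two reporting filters follow the published practice: interaction meta
results are dropped when one study's weight share strictly exceeds 50%;
stratified meta results with MAF < 5% are reported only when at least four
studies contributed and no study's share exceeds 30%. Both thresholds are
strict inequalities.

## Between-strata difference test

t = (β₁ − β₂)/√(SE₁² + SE₂² − 2·r·SE₁·SE₂), with one r per comparison: the
Spearman correlation of the meta-analysed betas across all QC-passing
shared SNPs (not per SNP). The reference distribution is the standard
normal by default — meta-analysed estimates have no natural small df, and
the published p-value for the strongest known gout locus is reproduced by
the normal tail — with a Student-t option of selectable df. Identical
estimates give t = 0, p = 1 even when the difference variance degenerates
(the identical-input guard); a non-positive variance with a non-zero
numerator is an error. Scans report the λ of the squared statistics, sort
by p, and flag rows below 10⁻⁵. Confidence intervals are reported as
β ± 2·SE, the convention used with these summary statistics. The
candidate-screen Bonferroni threshold is 0.05/(n_snps·n_comparisons).

## Interaction regression

Per SNP: z(residual) ~ μ + β₁BMI + β₂dose + β₁₂BMI·dose + ε, BMI
uncentered as published; a centering switch improves conditioning and maps
β₂ back by c·β₁₂ (β₁₂ and its SE are centering-invariant, verified to
1e-8). The "model-robust" SE is the HC0 sandwich
(X'X)⁻¹X'diag(e²)X(X'X)⁻¹ — the cited implementations do not state the HC
variant, so HC0, their default, is declared. Classical p-values use
t(n−4); robust p-values use the normal (the sandwich is asymptotic).
Mirroring robust-only software, the robust branch reports only β₁₂. The
fit is vectorised across SNPs through the b^k·g^l cross-product moments of
the 4×4 normal equations, so genome-wide scans cost a few matrix products;
both branches are tested to 1e-10 against explicit matrix oracles.

Under heteroskedastic noise proportional to BMI with β₁₂ = 0, the robust
branch's interaction λ sits closer to 1 than the classical branch — the
motivation for using it in follow-up waves.

## Circular genomic permutation

Analysed SNPs are ordered by (chr, pos) on a circle joining chromosomes
1..22. SNPs map to every gene interval (1-based inclusive; BED input is
converted) containing their position — no flanking window — and a pathway's
SNP set is the union over member genes, each SNP counted once per pathway.
The observed statistic is the count of pathway SNPs with p ≤ 0.05
(boundary counted). Each permutation rotates the p-vector by an offset in
1..M−1 (identity excluded); offsets are drawn with replacement unless the
requested number reaches M−1, in which case every distinct rotation is
used exactly once, enabling exact brute-force oracles.

The empirical p counts rotations with **at least** as many associated SNPs
as observed. The strictly-greater convention would make a fully null pathway maximally
significant — observed count 0, every rotation count also 0, no rotation
strictly exceeds the observation, p = 0 — which is pathological; ties-count-against is the declared default and ">" remains
an option. The tie convention makes the empirical p conservative by about
half the probability atom of the count distribution at the critical value;
the effect shrinks as pathways grow, which is why the null-uniformity
check uses large pathways (1000–3000 SNPs on a 50,000-SNP circle, 200
pathways, 1000 rotations): there the fraction of empirical p ≤ 0.05
averages ≈ 0.042 across seeds with SD ≈ 0.007, comfortably inside the
[0.03, 0.07] calibration band, whereas a few-hundred-SNP design averages
≈ 0.035 and fails the band regularly. Empirical p-values live on the
1/n_perm grid, are never negative, and equal 1 when the observed count
is 0.

## The synthetic consortium

The generator emulates what the analysis assumes, not more:

* Genotypes: per-SNP frequency f ~ Uniform(0.05, 0.95) shared across
  cohorts; hard-call dosages Binomial(2, f); SNPs independent (no LD);
  positions evenly spaced over 22 chromosomes for genome ordering. A
  fractional-dosage option shrinks hard calls toward 2f and records the
  variance ratio as the info metric so the QC path is exercisable.
* Individuals: unrelated; sex Bernoulli(0.5); age Uniform(30, 75); BMI
  Normal(sex mean ± cohort shift, SD 4.5 kg/m²) — male mean 27.5, female
  26.0, cohort shifts Uniform(−1.5, 1.5) — giving lean/overweight/obese
  splits of roughly 40/40/20, matching cohorts of westernised diet;
  two PCs with a mild BMI loading (0.03 per kg/m²) so PCs genuinely
  confound.
* Trait, on the z scale: 0.01/yr age, 0.8 male–female difference,
  0.1 per PC, 0.03 per kg/m² BMI, plus Σ(βⱼ + β₁₂ⱼ·BMI)·doseⱼ and
  N(0, 1) noise; mapped to mg/dl as 4.5 + 1.3·z. Effect vectors default
  to null; planted interaction effects use β₁₂ = 0.01 per allele per
  kg/m², the magnitude of the top published interaction loci.
* Reproducibility: one master seed fixes the shared panel and cohort BMI
  shifts; cohort i uses seed + i + 1. Reruns are bitwise identical.

What passing tests on this generator do **not** show: robustness to LD
(rotation preserves local correlation, but there is none to preserve
here), imputation error structure, relatedness, population stratification
beyond linear PC confounding, or X-chromosome effects.

## Study sizes used in the self-checks

The null-calibration consortium is 5 cohorts × 2000 individuals × 5000
SNPs; the difference-scan type-I error uses the lean-vs-obese metas of
that run; interaction uniformity pools the five per-cohort scans. CI
coverage uses 200 single-cohort replicates (n = 2000). The
opposite-effects power check plants one SNP whose BMI-linear allelic
effect equals +0.2 at BMI 21.5 and −0.2 at BMI 33 in a 2000-SNP consortium
and requires it to rank first in the lean-vs-obese scan. These sizes keep
each suite in minutes while leaving the calibration bands well inside
binomial resolution.

## Known limitations

* Fixed-effects pooling only; no random-effects or meta-regression.
* The mixed-model branch for related individuals is out of scope; PC
  adjustment stands in.
* Genomic control corrects only upward (λ > 1), so null-data meta λ sits
  slightly below 1 (~0.95 at 5000 SNPs) — a property of the procedure, not
  a bug.
* Exact reproduction of published per-SNP difference p-values from rounded
  printed betas/SEs is not possible (back-calculated r is unstable under
  printing precision); the worked examples therefore use r = 0, which
  reproduces the published rounding.
* The pathway stage uses synthetic gene intervals and gene sets; no live
  KEGG retrieval or curated gene models.
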