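# Methods

## The bivariate association model

Each individual contributes a two-dimensional phenotype
**y**ᵢ = (y₁ᵢ, y₂ᵢ)′ modelled as

**y**ᵢ = **μ** + **B**′**z**ᵢ + **β** xᵢ + **ε**ᵢ,  **ε**ᵢ ~ N₂(0, Σ),

with xᵢ the additive minor-allele dosage (0/1/2) and **z**ᵢ covariates.
The SNP test compares the residual sum-of-squares-and-cross-products
(SSCP) matrix E of the full model with E + H of the null model
(**β** = 0) through Wilks' Λ = |E|/|E + H|, an equivalent monotone
transform of the Gaussian likelihood ratio (Λ = (L₀/L₁)^(2/n)). For one
hypothesis degree of freedom and two responses, the Rao conversion

F = ((1 − Λ)/Λ) · (νₑ − 1)/2 on (2, νₑ − 1) df, νₑ = n − rank([1, Z, x]),

is exact, not asymptotic: the reported p-value is the exact finite-sample
upper tail under Gaussian errors. The test suite verifies exactness two
ways — agreement with an independently coded normal-equations/determinant
computation to 1e-8, and the simulated null F mean matching
df₂/(df₂ − 2). Univariate tests are OLS t-tests fitted via statsmodels.

Assumptions worth keeping in mind: Gaussian residuals (moderate
violations matter little at n in the hundreds, by the usual linear-model
robustness), additivity of the allele effect, and homogeneous effects
across the sample after covariate adjustment.

### Missing data and degenerate inputs

Listwise deletion per SNP; the analysed n is reported in every scan row.
A SNP constant among analysed samples, or one perfectly collinear with
covariates, raises `MonomorphicError` rather than returning p = 1.
Identical (or perfectly collinear) traits make E singular and raise
`DegenerateResidualError`; in the scan both become NaN rows with a
reason code. Λ is clamped to ≤ 1 against round-off, and a perfect fit is
declared when the residual sum of squares falls below 1e-12 of the total
sum of squares.

## Covariate adjustment and stratification

Phenotypes are pre-adjusted: each trait is replaced by its least-squares
residual on intercept + age + sex + the top k genotype principal
components (default k = 10), and the scan then runs with no further
covariates. A joint-covariate mode (covariates inside each SNP
regression) is available in `assoc.scan`. PCA uses mean imputation of
missing dosages, centring at 2p̂ and the variance-stabilising scale
√(2p̂(1 − p̂)) (plain covariance scaling via `scale="cov"`); components
come from a seeded randomized SVD, unit-norm with a deterministic sign
convention. Zero-variance SNPs are dropped from PCA with a log entry.

Pre-adjusting only the phenotype (not the genotype) slightly deflates
test statistics when the tested SNPs themselves carry strong structure;
at the mild divergence typical of a single self-identified ethnic cohort
(FST ≈ 0.02 between recruitment sites) the genomic inflation factor λ on
structured null simulations returns to 0.95–1.10 with 10 PCs, from > 1.2
uncorrected — the calibration the test suite checks. At much larger FST
the joint-covariate mode is the better choice.

## Femoral-neck geometry from DXA

DXA supplies areal BMD (g/cm²) and projected area (cm²) over the
femoral-neck scan region. The derivation treats the neck cross-section
as a circular annulus:

* W = area / H (H = scan width along the neck axis, default 1.5 cm)
* CSA = BMD · W / ρₘ (ρₘ = 1.053 g/cm³, effective mineral density of
  fully mineralised bone)
* outer radius r₀ = W/2; inner radius rᵢ = √(r₀² − f_cort·CSA/π), with
  f_cort = 0.6 the fraction of mineralised area assigned to the cortical
  shell; CT = r₀ − rᵢ; BR = r₀/CT; Z = (π/4)(r₀⁴ − rᵢ⁴)/r₀.

All three parameters are configurable. With the defaults, the reference
adult male means (W = 3.54 cm, CSA = 2.92 cm²) give CT = 0.165 cm and
BR = 10.71, within 3% of the published 0.17 and 10.97 — supporting the
calibration. The annulus Z (≈ 1.41 cm³ at those means) sits below
published hip-structural-analysis values (≈ 1.84 cm³), which derive Z
from the full mass profile rather than an annulus; Z here is the annulus
approximation only, and analyses of Z should treat its scale as
model-specific. Records whose annulus is impossible
(f_cort·CSA/π > r₀²) or degenerate (CT = 0) are flagged invalid and
excluded from association with a logged count — never imputed.

ALM is the sum of arm and leg lean soft-tissue mass.

## Quality control

The default HWE test is the exact conditional test: given the observed
allele counts, heterozygote counts are enumerated by the standard
recurrence and the two-sided p is the summed probability of all
configurations no more probable than the observed one (no mid-p
correction) — robust at MAF near the 1% cut, where the chi-square
approximation (also provided) is unreliable. Filters use strict
inequality (fail iff p < 0.01, iff MAF < 0.01, both thresholds
configurable); MAF is computed on non-missing genotypes, with allele
labels swapped (and the swap recorded) if the designated allele exceeds
0.5. Monomorphic SNPs get p = 1 by convention; all-missing SNPs fail the
MAF criterion. The report always satisfies
retained = total − hwe_fail − maf_fail + both_fail.

## Meta-analysis and LD

Fisher's method: X = −2Σln pᵢ ~ χ² with 2k df under the joint null.
Inputs must lie in (0, 1]; p = 0 is rejected rather than silently
truncated. The statistic ignores cohort sizes and input order, and the
combined p is strictly monotone in every component.

Pairwise LD from unphased dosages uses the classic two-locus EM: the
double heterozygote is the only phase-ambiguous configuration, and its
expected split between cis (AB/ab) and trans (Ab/aB) phasings is updated
from the current haplotype frequencies. Initialisation at
linkage-equilibrium products; convergence when the log-likelihood change
drops below 1e-10 (cap 1000 iterations); the log-likelihood is asserted
non-decreasing every step. D = p_AB − p_A·p_B, D_max is the bound
implied by the allele frequencies on the relevant side, and D′ = |D|/D_max
is reported unsigned in [0, 1] (the Haploview convention). With no
double heterozygotes the EM reduces exactly to direct haplotype
counting, which the suite checks. Both loci must be polymorphic with at
least 10 jointly observed samples.

## The synthetic-data generator

The generator is the package's test bed and emulates exactly the
structure the analysis assumes:

* **Genotypes.** Within each subpopulation, unblocked SNPs are binomial
  (HWE) at a Balding–Nichols frequency — Beta(p(1−F)/F, (1−p)(1−F)/F)
  around the panel MAF — giving the minimal-parameter divergence that
  PCA must absorb. LD blocks are finite haplotype pools; the default
  pool holds the two complementary haplotypes, so every within-block
  pair has D′ = 1, the qualitative signature of a tight block.
  Missingness is off by default (MCAR rate optional). Panels default to
  ~4 kb spacing to match dense-array marker density; tests use panels of
  50–2000 SNPs, a deliberate scale-down of genome-wide panels that
  leaves every per-SNP computation identical.
* **Traits.** Bivariate Gaussian with configurable residual cross-trait
  correlation (reported lean-mass/geometry correlations span roughly
  0.45–0.77, with ALM–BR near −0.1; tests default to 0.5), age uniform on [20, 65],
  sex Bernoulli, and additive per-allele effects in trait-SD units,
  shared, trait-specific or null.
* **Raw DXA.** Sex-specific Gaussian BMD/area/lean masses calibrated so
  the derived traits land at adult reference scale (male W ≈ 3.54 cm,
  ALM ≈ 24 kg; female W ≈ 3.12 cm, ALM ≈ 15.8 kg); trait covariance
  beyond those means is not calibrated to any cohort's raw data.

What the generator does **not** emulate: realistic recombination maps or
LD decay with distance, genotyping error and batch effects, relatedness,
non-Gaussian trait tails, assortative structure beyond discrete demes.
Passing tests therefore demonstrate correctness of the statistical
machinery under its stated model, not robustness to every real-data
pathology.

## Experiment sizes and numerical choices

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the asserted margins while keeping the suite quick: type-I
error over 2000 null SNPs at n = 1000 (binomial 95% half-width ±0.0096
around 0.05); power cells at 300–500 replicates (MC SE ≤ 0.023); effect
recovery over 60 replicates at n = 2000; D′/EM checks at n = 700–2000.
The genomic-control scenario uses two demes at FST = 0.02 with an
0.8-SD trait shift, which makes uncorrected λ > 1.2 while staying inside
the regime where phenotype-only PC adjustment is calibrated (see above).
All randomness flows from explicit seeds; identical inputs give
byte-identical outputs, including file round-trips.

File I/O uses a text PLINK-style `.ped`/`.map` dialect (documented in
`pipeline.py`) for desk-scale inspectability; heterozygotes are written
in alphabetical allele order so the files do not depend on which allele
is designated minor, making write→read→write byte-stable. Ties at
MAF = 0.5 resolve the minor label to the lexicographically smaller
allele.

## Known limitations

* Two traits only; no >2-trait multivariate extension, dominance or
  interaction models.
* The scan reports raw p-values with fixed reporting thresholds (10⁻⁵
  and 10⁻⁴ tables), mirroring common GWAS reporting; Bonferroni columns
  are available as a clearly-labelled extension.
* No genomic-control rescaling, LD pruning before PCA, mixed-model
  association, or block partitioning (Gabriel rules); D′ matrices are
  reported raw.
* Desk-scale performance envelope (~10⁴ SNPs × 5×10³ samples); the scan
  loops SNPs in Python and is not engineered for genome-scale panels.
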