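# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `devgen`, in the order the pipeline runs
them.

## Synthetic cohorts

The generator emulates a cross-sectional, population-based developmental
cohort: nuclear families (two founder parents plus a Poisson number of
children, mean 2 by default) and unrelated singletons, everyone with sex
and an age drawn uniformly on [8, 21] years.  Ages are cross-sectional —
one age per person — because the identifying information for age-varying
genetic models comes from *related pairs observed at different ages*, not
from repeated measures.  Parents receive ages from the same distribution as
everyone else: the pedigree encodes relatedness, not a literal genealogy.

**Genotypes** are gene-dropped: founder haplotypes are drawn per SNP from
Hardy–Weinberg at a MAF uniform on [0.05, 0.5]; within an LD block (10 SNPs
sharing one MAF by default) each haplotype copies the previous allele with
probability 0.8, so adjacent-dosage correlation is ≈ 0.8 and r² decays
geometrically within the block — the simplest mechanism that gives LD
pruning something real to do.  Children receive one uniformly segregated
allele per parent per SNP (no crossover map; realized relatedness then has
slightly less variance than with linked transmission, which is conservative
for every test here).  The default SNP count is 50,000, matching the scale
of a common-variant panel; tests and the acceptance script use 2,000–12,000
and state so below.

**Phenotypes.**  Seven latent traits (five psychopathology factors plus
cognitive ability and speed) are drawn jointly per family block from a
multivariate normal whose genetic part is the trait-correlation matrix
Kronecker the age-decayed kinship kernel, scaled by per-trait age-varying
genetic SDs, and whose environmental part is independent across
individuals.  Externalizing carries the full Gene × Age truth
(σ²_g0 = 0.46, σ²_e0 = 0.54, γ_g = −0.146, γ_e = 0.059, λ = 0.027 per
year); the other factors are static with h² of 0.21 (general), 0.09
(anxious-misery), 0.04 (fear), 0.00 (psychosis), and the cognitive latents
0.50 (ability) and 0.30 (speed).  The genetic correlation between
externalizing and ability defaults to −0.394.  A single decay rate λ (the
externalizing value) is applied to all genetic blocks of the joint draw; a
trait-specific decay would break the Schur/Kronecker argument that keeps
the joint covariance provably PSD, and every other trait is static anyway.

**Items.**  Symptom items follow a probit bifactor model: item *j* of
subject *i* is endorsed with probability Φ(L_j·η_i − τ_j).  The default
battery has 112 items split 34/30/26/22 across anxious-misery,
externalizing, fear, and psychosis-spectrum (a representative split — any
item → domain mapping can be supplied), standardized loadings 0.6 on the
general factor and 0.4 on the domain.  Thresholds are calibrated through
the marginal probit integral, τ̃_j = −Φ⁻¹(target), so each domain hits its
marginal endorsement target — 21% externalizing, 15% anxious-misery, 16%
fear, 11% psychosis-spectrum — *including* the loading-induced variance.

**Cognition.**  14 accuracy and 14 reaction-time columns load 0.8 on the
ability and speed latents respectively; 10% of cognitive entries are then
removed completely at random.  Larger reaction times mean slower
responding; the PCA composite's orientation anchor makes that sign
convention explicit.

What the generator does **not** emulate: realistic human LD maps,
ascertainment and screening effects, assortative mating, the X chromosome,
rater effects, and non-normal trait distributions.  Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to all features of real data.

## Relatedness

The empirical GRM is the standard allele-frequency-standardized estimator,
K_ij = (1/M) Σ_m (x_im − 2p_m)(x_jm − 2p_m) / (2p_m(1 − p_m)), with sample
allele frequencies, monomorphic SNPs skipped, and pairwise-complete
averaging over missing dosages (unbiased under MCAR).  It sits on the same
2Φ scale as the pedigree numerator-relationship matrix (recursive kinship
algorithm), so either feeds the models unchanged; no rescaling of σ²_g is
applied.  LD pruning is a greedy left-to-right windowed scan (drop the
later SNP of any pair with r² above the threshold, default 0.1, window 50),
verified against an exhaustive pairwise oracle on small instances.

**Relatedness cutoff.**  At desk-scale SNP counts the off-diagonal noise of
the GRM (SD ≈ 1/√M) dominates the true relatedness of unrelated pairs and
attenuates ML heritability badly (measured: ĥ² = 0.07 at M = 189 versus
0.48 with pedigree kinship).  The pipeline therefore zeroes |K_ij| below
max(0.05, 4/√M) before model fitting — the family-data practice of treating
below-threshold pairs as unrelated.  This restores family-block structure
(which the likelihood engine also exploits for speed) and recovers the
pedigree-matched estimate (0.45 at M = 1,416).  GRM files are written in
the GCTA lower-triangle text dialect (plus id file) or as a square TSV;
matrices are checked for symmetry, PSD within 1e−8, trace ≈ N, and
off-diagonals within [−0.2, 1.2] (range bounds are conventions, settable).

## Psychometrics

Estimation is two-stage: pairwise ML tetrachoric correlations (thresholds
from the margins, bivariate-normal orthant probabilities via Owen's T
function), then unweighted least squares on the tetrachoric matrix for the
confirmatory structure.  ULS on tetrachorics estimates the same parameters
as weighted least-squares approaches, at the cost of efficiency rather than
consistency, so recovered loadings are comparable in pattern but not
digit-for-digit with weighted fits.  Identification: factor variances fixed
at 1, one sign constraint per factor (largest loading positive); 5 seeded
multi-starts.  A 1e−3 ridge on the loadings pins the multiplicative flat
direction that appears when a factor's other loadings vanish (a specific
loading enters the fit only through products); the measured recovery bias
is ≪ 0.001.  Degenerate 2×2 tables (empty discordant or concordant cells)
return ±1; items with 0% or 100% endorsement are flagged unusable.

Under a *null* specific factor, ULS specific loadings absorb tetrachoric
sampling noise up to the rank-1 scale of the within-domain noise block
(mean ≈ 0.12, occasional loadings ≈ 0.5 at n = 4,000 with 6 items per
domain).  This is a property of any two-stage estimator at this design,
not an implementation artifact; the tests pin specifics to that noise level
while requiring clean recovery of the general factor.

**Scores** are per-subject MAP estimates under the probit likelihood with a
standard-normal prior, computed by vectorized Fisher scoring to gradient
norm < 1e−6; missing items drop out of the likelihood, all-missing subjects
get missing scores.  Raw MAP scores under a bifactor model are mildly
correlated in-sample (up to |r| ≈ 0.3 even when scoring with the true
model) because general and specific factors share items.  Since the whole
point of the bifactor decomposition is orthogonal scores, a decorrelation
step follows: the general column is kept as-is, the specific columns are
residualized on it and symmetrically (ZCA) whitened.  Measured effect:
cross-correlations ≈ 0, general-score truth correlation 0.86 (24 items) /
0.92 (112 items), specifics ≈ 0.6 at 112 items.  Hierarchical models are
scored through their Schmid–Leiman orthogonalization (which leaves the
implied item correlations unchanged) and skip the decorrelation step.

## Trait preparation

Eligibility keeps subjects missing strictly less than 50% of cognitive
entries; filtering precedes imputation.  Imputation is single-table MICE
with predictive mean matching: 10 chained passes of per-column OLS on age,
sex, and the other cognitive columns, each missing entry replaced by the
observed value of one of the 5 donors with the closest predicted means.
PMM keeps imputed values inside the observed support; observed entries are
never altered.  The `g` and `gs` composites are the first principal
component of the standardized accuracy and reaction-time columns, scaled to
unit variance and sign-anchored (first column by default).  The covariate
design is intercept, age_c, age_c², sex, age_c×sex, age_c²×sex with age
centered at the sample mean; sex² is degenerate and excluded.  Before
model fitting every analysis trait is rank-based inverse-normal transformed
(Blom offset, average ranks for ties).

## Variance components

All models are fitted by full maximum likelihood with fixed effects
profiled out by GLS — ML rather than REML so that nested LRTs are exact
likelihood comparisons (REML is available for the univariate model).  The
engine decomposes the relatedness matrix into connected components and
batches equal-sized blocks through LAPACK; a dense matrix degrades to a
single block, and the univariate model additionally uses a (blockwise)
eigendecomposition so that the fit reduces to a 1-D bounded maximization
over h² with the total variance and β in closed form.

The Gene × Age likelihood is maximized by L-BFGS-B with analytic gradients
over (α_g, γ_g, α_e, γ_e, λ), λ bounded in [0, 2] on the raw scale so the
boundary λ = 0 is attainable; the moment-based start comes from the static
polygenic fit, plus 2 further seeded perturbed starts by default.  When a
constrained null fit ends above the incumbent full fit (a local-optimum
symptom), the full model is automatically refit from the null's solution
before the LRT is formed.  Bivariate fits parameterize variances on the log
scale and correlations by Fisher's z; with complete data the stacked
likelihood reduces to per-individual 2×2 blocks after rotation by the
eigenvectors of K, and with partially missing traits it falls back to exact
per-family evaluation over the observed entries.

Null distributions: χ²₁ for interior parameters (γ_g, γ_e, ρ_g, ρ_e) and
the ½χ²₀ + ½χ²₁ mixture for parameters tested on their boundary (h² = 0,
λ = 0).  Measured type-I error at α = 0.05 over 400 null simulations:
0.045 for both the h² and γ_g tests.  Standard errors come from the
observed information (central finite differences on the transformed scale)
with delta-method back-transforms; the λ row is dropped from the
information when λ̂ sits on its boundary.  BH-FDR at q = 0.05 is applied in
three separate families mirroring the analysis: the heritability screen,
the genetic correlations, and the G×A parameters.  Environmental variance
absorbs everything non-genetic, including measurement error; no attempt is
made to separate them.

λ is weakly identified in cohorts with a single relative class and narrow
within-family age spread (it can pin at its upper bound, which raises a
warning); cohorts mixing relationship classes and age gaps identify it
better.

## Pipeline

Stages run in order: simulate → factor scores → trait preparation → GRM →
heritability screen → genetic correlations → Gene × Age → report.
Bivariate and Gene × Age fits are scheduled only for traits passing the
FDR-corrected heritability screen; correlation pairs are factor ×
cognitive-composite, both passing.  Every run writes its artifacts with a
manifest of SHA-256 hashes; reruns with the same configuration and seed are
byte-identical.  All randomness descends from a single seed through spawned
seed sequences.

## Problem sizes

The test suite and acceptance script scale the study down to desk size, as
their own design choice: recovery studies use N = 1,500–2,000 (300 sib
quads + 800 singletons, or 250 four-child families), 20 replicates;
calibration studies use 400 simulations at N = 500; GRM studies use
2,000–10,000 SNPs; the end-to-end acceptance run uses ≈ 1,500 subjects,
112 items, and 12,000 SNPs.  At these sizes the full suite runs in about a
minute and the acceptance script in under one minute on one CPU.

## Known limitations

* Factor-score heritabilities are attenuated relative to the latent truth
  by score unreliability (roughly the squared score–truth correlation), as
  with any factor-score-based analysis; the acceptance output reports the
  estimates for the *scores*, not the latents.
* The empirical-GRM path needs either large SNP counts or the relatedness
  cutoff; with both small M and no related pairs the variance components
  are essentially unidentified.
* No shared-environment or dominance components; no GWAS; no
  ancestry/stratification handling (the synthetic cohort is homogeneous).
* The bivariate missing-data path is exact but loops over family blocks in
  Python; it is intended for moderate N.
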