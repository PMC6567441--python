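# Methods

This note records the models implemented in `microherit`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## The animal model and heritability

Each microbial feature (log10 relative abundance of a taxon, an alpha
diversity index, a principal-coordinate score, or a log abundance ratio)
is treated as a quantitative trait `y` of the host and modeled as

    y = mu + breed + sex + diet + b*age + a + e,
    a ~ N(0, sigma_a^2 G),   e ~ N(0, sigma_e^2 I),

where `G` is the VanRaden method-1 genomic relationship matrix built from
QC-passing SNP dosages, `Z = M - 2p`, `G = ZZ' / (2 sum p_k (1-p_k))`,
with allele frequencies `p` observed in the analyzed panel.  Narrow-sense
heritability is `h2 = sigma_a^2 / (sigma_a^2 + sigma_e^2)`; a feature is
called heritable at `h2 >= 0.15` and enters the GWAS at `h2 >= 0.1`
(both thresholds inclusive and configurable).

Variance components are estimated by REML through a single spectral
decomposition of `G` (the EMMA device): rotating `y` and the design into
the eigenbasis makes the covariance diagonal for every value of the
variance ratio `lambda = sigma_a^2 / sigma_e^2`, so the restricted
likelihood can be profiled over `lambda` alone.  The profile is scanned
on a 50-point log grid over [1e-5, 1e5] and refined with bounded Brent
search; with one genetic component this is exact and global, avoiding the
convergence failures of iterative AI-REML on boundary traits.  When the
optimum pins `lambda` at the lower bound the fit is re-evaluated exactly
at `lambda = 0` and flagged as a boundary solution.  The rotated profile
value equals a direct dense-matrix evaluation of the restricted
log-likelihood (tested to 1e-6 on random instances), so the rotation is
an implementation detail, not an approximation.

`se(h2)` comes from the numerical curvature of the profile restricted
likelihood in `h2` (delta method, central differences with step 1e-3;
one-sided at boundaries).  This approximates, but does not replicate, the
average-information standard errors of general-purpose mixed-model
software.  At the default acceptance design (650 animals in 50 half-sib
families, 5,000 markers) these SEs are ~0.07-0.09, which also sets the
floor on per-replicate estimation error: an unbiased estimator with
sampling SD ~0.085 has expected absolute error ~0.07.  The recovery
simulations therefore assess unbiasedness of the replicate mean and 2-SE
interval coverage; single-replicate errors cannot be pushed below that
floor by any estimator at this design.

Samples missing the trait, any fixed-effect level, or the GRM are
dropped per trait (the model simply has fewer records).  Fixed effects
use treatment coding against the alphabetically first level; columns
aliased by nesting (e.g. a diet fed to one sex only) are detected by
greedy rank inspection and dropped with a warning.

## Mixed-model GWAS

Traits are first adjusted to OLS residuals on the fixed-effect design,
then each mapped marker is tested as a fixed effect in an animal model
with a grand mean, genotypes coded -1/0/1 (aa/Aa/AA).  The default P3D
mode estimates `(sigma_a^2, sigma_e^2)` once under the marker-free null
and reuses them for every marker, reducing each test to generalized
least squares in the rotated basis (vectorized over markers); `exact`
mode re-profiles the variance ratio per marker and agrees with P3D in
p-value ranking (rho > 0.99 in tests).  P-values use the t distribution
with `n - 2` degrees of freedom — the reference software does not state
its null distribution, so this conservative choice is documented rather
than assumed.  Per trait, p-values are converted to genome-wide FDRs by
Benjamini-Hochberg; associations are tiered significant (FDR < 0.1) or
suggestive (0.1 < FDR < 0.2), with strict boundaries as printed in the
result schema.  Markers without a map position stay in the GRM but are
excluded from the scan.  Monomorphic markers are emitted flagged with
beta 0 and p 1 rather than dropped, keeping marker bookkeeping exact.

## SNP quality control

Markers are retained when HWE p > 1e-6 (one-df chi-square at the observed
allele frequency), MAF >= 0.05, and call rate >= 0.90; the removal report
lists every failed criterion per marker.  Missing genotypes are imputed
by marker mean (2p) by default — deterministic and adequate below ~10%
missingness — with a seeded random mode drawing from observed genotype
frequencies as an alternative.  X-linked markers are treated as autosomal
dosages.  Centering frequencies come from the post-QC observed data, not
an external reference.

## Diversity

Alpha indices are bias-corrected Chao1, Shannon (base 2, matching the
legacy QIIME behavior; natural log available), Simpson (`1 - sum p^2`),
and Good's coverage, computed per rarefaction iteration and averaged
(the aggregation across the 100 subsampling iterations is not specified
by convention; the mean is used).  Rarefaction subsamples without
replacement (multivariate hypergeometric), excludes samples under the
depth, and reports them.  Beta diversity is Bray-Curtis; PCoA performs
Gower double-centering and eigendecomposition, takes coordinates only on
positive eigenvalues, and reports explained fractions over the positive
spectrum with no Lingoes/Cailliez correction.  PCoA runs on a single
seeded rarefaction by default (iteration-averaged distances are not
used); the choice is recorded in the run manifest.

PERMANOVA uses Anderson's pseudo-F on squared distances with raw-label
permutations and the add-one p-value estimator
`(1 + #{F_perm >= F_obs}) / (1 + B)`, so p is never 0.  Strata restrict
permutations to within-stratum shuffles (the nested sex-within-diet
design needs this).  Note a structural property of permutation tests:
when a permuted labeling reproduces the observed partition it ties with
the observed statistic and is counted, so the attainable minimum p is
bounded by the partition recurrence rate, not by `1/(B+1)`.

## SparCC

Basis correlations are estimated from log-ratio variances
`t_ij = var(log x_i / x_j)` under the sparsity assumption: row sums of
`t` give a linear system `(diag(d_i - 1) + A + I) omega = t` rowsums for
the basis variances, solved directly; correlations follow as
`(omega_i + omega_j - t_ij) / (2 sqrt(omega_i omega_j))`, clipped to
[-1, 1].  The strongest pair exceeding |r| > 0.1 is excluded from the
system and the solve repeated, up to 10 rounds (stopping early if any
taxon would drop below 3 included partners).  Fractions are estimated
per inner iteration as a Dirichlet posterior draw with an add-one prior
(20 iterations, median aggregation); a deterministic add-one-pseudocount
mode exists for exact tests.  Permutation p-values shuffle each taxon's
counts across samples independently (margins preserved, all between-taxon
association destroyed) and use the add-one estimator, two-sided.

Two properties of this estimator are worth stating plainly.  First,
compositional invariance to per-sample total rescaling is exact only in
the infinite-depth limit: any pseudocount ties the fraction estimate to
the total.  Second, finite sequencing depth attenuates correlations
involving rare taxa — at depth 2,000 with a realistically uneven
composition (log-normal basis, unit log variance), a planted basis
correlation of 0.7 between randomly chosen taxa is estimated around
0.55-0.61 on average, while feeding the solver exact basis fractions
recovers 0.70.  The unit suite separates these effects with an
exact-fraction oracle; the acceptance simulation reports the attenuated
estimate under the study's depth as measured.

The network keeps edges with |r| > 0.3 and p < 0.001 (strict), after a
prefilter that drops samples under the domain depth (2,000 for bacteria,
500 for archaea), eliminates taxa present in under 20% of retained
animals, and then subsamples once to the depth — in that order, so every
analyzed row sums to the depth exactly.

## Feature engineering

Rank collapsing sums counts sharing a lineage label, pooling taxa
unclassified at the target rank under `unclassified <nearest classified
parent>`; per-sample totals are conserved exactly.  Detected taxa must
exceed 0.5% relative abundance in at least one sample AND 20% prevalence,
both strictly.  log10 transformation of relative abundances treats zeros
as missing by default (the animal model then uses fewer records, matching
the variable per-feature n of real cohorts); a half-minimum pseudocount
policy is available.  Outlier removal is a single pass at mean +/- 3 SD
computed once on the non-missing values — not iterated, since the
screening is described as a one-time step before analysis.  All
transforms append to the trait's provenance log.

## Host traits and screens

FCR = DMI/ADG; RFI is the within-cohort OLS residual of DMI on ADG and
metabolic weight, with RFIf adding backfat to the regression — a
deliberate simplification of the multi-season adjustment procedures used
on real feedlot data.  Heritable features (h2 >= 0.15) are screened
against feed-efficiency traits and VFA measures by average-rank Spearman
correlation with t-approximation p-values, pairwise-complete samples,
and a minimum of 5 shared records per pair; constant vectors yield
missing correlations rather than errors.

## Synthetic cohorts

The generator emulates the study conditions end to end: ~650 animals in
50 half-sib families (sires' gametes transmitted marker-independently;
dams unrelated), ~2,000-42,000 biallelic SNPs on 30 chromosomes with MAF
drawn from [0.05, 0.5], breed (3) / sex (3) / diet (4) factors with an
age covariate near 293 days, additive-genetic variance fractions in the
0-0.25 range, and compositional tables as multinomial draws at depths
~2,000/500 from log-normal basis abundances with a requested correlation
structure (Dirichlet-multinomial overdispersion optional).  Half-sib
pairs have expected additive relationship 0.25 and unrelated pairs 0,
which the VanRaden GRM reproduces; this gives the eigenvalue spread REML
needs.  What the generator does not model: linkage disequilibrium beyond
family co-inheritance, breed-specific allele-frequency divergence,
mutation/recombination realism, taxon-abundance zero inflation beyond
what the log-normal/multinomial induces, and any genotype-microbiome
confounding through shared environment.  Passing tests therefore
demonstrate correctness of the estimators under the stated generative
models, not robustness to the full messiness of field data.

## Problem sizes in the test and acceptance runs

Recovery simulations use 20 cohorts of 650 animals with 5,000 markers
(heritability) and one cohort with 2,000 markers and 20 trait replicates
(GWAS power); SparCC checks use 50-100 taxa, 100 samples, depth 2,000,
with 1,000 permutations for calibration; the end-to-end run uses 200
animals, 2,000 markers, 60 taxa, and 200 network permutations.  These
sizes keep the full suite around a minute on one core while leaving
every statistical check adequately powered; the paper-scale settings
(42k markers, 10k permutations) remain the library defaults where the
original protocol states them.
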