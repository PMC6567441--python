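# microherit

Quantitative genetics of host-associated microbial communities: does the
host's genome shape which microbes it carries?  `microherit` implements
the full analysis chain used to answer that question in livestock
microbiome studies — from a taxon count table, a SNP panel, and sample
metadata to heritability estimates, microbiome GWAS hits, co-occurrence
networks, and screens against production traits — together with a
synthetic-cohort generator so every stage is testable with known ground
truth.

It is written for animal and microbiome scientists who have 16S (or
metagenomic) taxon counts and medium-density genotypes for the same
animals and want to ask, per microbial feature: how much of its
variation is additive-genetic, which SNPs associate with it, and whether
the heritable features track feed efficiency or rumen fermentation.

## The models

**Heritability.**  Each microbial feature *y* (log10 relative abundance,
alpha diversity, PCoA score, or a log abundance ratio) is fit with a
genomic animal model

&nbsp;&nbsp;&nbsp;&nbsp;*y* = *μ* + breed + sex + diet + *b*·age + *a* + *e*,
&nbsp;&nbsp;*a* ~ N(0, *σ*<sub>a</sub>² **G**), &nbsp;*e* ~ N(0, *σ*<sub>e</sub>² **I**),

with **G** the VanRaden genomic relationship matrix
(**G** = **ZZ**′ / 2Σ*p*(1−*p*), **Z** = **M** − 2*p*) built from
QC-passing SNPs (HWE p > 10⁻⁶, MAF ≥ 5%, call rate ≥ 90%).  REML runs by
spectral decomposition of **G** with a 1-D profile search over
*σ*<sub>a</sub>²/*σ*<sub>e</sub>² — exact for a single genetic
component — and *h*² = *σ*<sub>a</sub>²/(*σ*<sub>a</sub>² + *σ*<sub>e</sub>²)
with a delta-method SE.  Features with *h*² ≥ 0.15 are called heritable.

**GWAS.**  Features with *h*² ≥ 0.1 are adjusted to fixed-effect
residuals, then every mapped marker (coded −1/0/1) is tested in the
animal model (P3D: null variance components reused per marker).
Per-trait Benjamini–Hochberg FDRs tier associations as significant
(FDR < 0.1) or suggestive (0.1 < FDR < 0.2).

**Community structure.**  Rarefied alpha diversity (Chao1, Shannon,
Simpson, Good's coverage), Bray–Curtis PCoA, PERMANOVA with optional
permutation strata, SparCC compositional correlation networks
(|r| > 0.3, permutation p < 0.001), and Spearman screens of heritable
features against feed-efficiency traits (FCR, RFI) and volatile fatty
acids.

## Worked example

Simulate a 650-animal half-sib cohort (50 sires × 13 offspring, 5,000
SNPs), a trait with true *h*² = 0.25, and recover it:

```python
from microherit import synthdata, genoqc, varcomp, gwas

ped = synthdata.PedigreeStructure(n_sires=50, offspring_per_sire=13)
panel = synthdata.simulate_genotypes(ped, n_markers=5000, seed=7)
grm = genoqc.build_grm(panel)
meta = synthdata.simulate_metadata(panel.sample_ids, seed=8)
design = varcomp.build_design(meta)       # breed + sex + diet + age

truth = synthdata.SimTruth(sigma_a2=0.25, sigma_e2=0.75)
trait = synthdata.simulate_polygenic_trait(grm, design, truth, seed=9)
fit = varcomp.fit_animal_model(trait, design, grm)
print(f"h2 = {fit.h2:.3f} +/- {fit.se_h2:.3f}  "
      f"(sigma_a2={fit.sigma_a2:.3f}, sigma_e2={fit.sigma_e2:.3f}, n={fit.n_used})")
print("heritable at 0.15:", varcomp.classify_heritable(fit))
```

```
h2 = 0.329 +/- 0.088  (sigma_a2=0.320, sigma_e2=0.652, n=650)
heritable at 0.15: True
```

The estimate (0.33 ± 0.09) covers the simulated 0.25 within one standard
error; at this cohort size the SE of *h*² is ~0.07–0.09, so single
estimates scatter accordingly while the average over replicate cohorts
is unbiased.  Planting a causal SNP that explains 5% of trait variance
and scanning finds it:

```python
qtl = synthdata.simulate_qtl_trait(panel, grm, panel.marker_ids[2500], 0.05,
                                   synthdata.SimTruth(sigma_a2=0.15, sigma_e2=0.85),
                                   seed=10)
adjusted = gwas.adjust_phenotype(qtl, design)
scan = gwas.mixed_model_scan(adjusted, panel, grm)
top = scan.nsmallest(1, "p_value").iloc[0]
print(f"top hit: {top.marker_id} (chr{top.chromosome}:{int(top.position)}) "
      f"p={top.p_value:.2e} FDR={top.fdr:.2e} tier={top.tier}")
```

```
top hit: snp4875 (chr15:95179516) p=5.07e-09 FDR=2.53e-05 tier=significant
```

Marker 2500 of the shuffled map is `snp4875` — the planted SNP, detected
genome-wide significant.

A command-line interface mirrors the library
(`microherit simulate|features|diversity|qc|grm|h2|gwas|network|run`);
`microherit run --config run.cfg` executes the whole chain from TSV
inputs and writes a heritability table, an association table, a network
edge list, a correlation screen, and a provenance manifest with output
hashes.

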