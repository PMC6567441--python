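"""Synthetic cohorts with known genetic and compositional ground truth.

Emulates the study conditions of a multi-breed beef-cattle cohort:
half-sib families genotyped on a medium-density SNP panel (~42k markers
on 30 chromosomes, MAF >= 0.05), microbial features with additive-genetic
variance fractions in the 0-0.25 range under breed/sex/diet/age fixed
effects, and compositional count tables (log-normal basis + multinomial
sampling) with planted basis correlations.

Relatedness comes from half-sib families: each sire's gametes are
transmitted to its offspring (markers independent given parental origin,
i.e. no linkage disequilibrium beyond family co-inheritance), dams are
unrelated population draws.  Half-sib pairs then have expected additive
relationship 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .features import TaxonCountTable, TraitVector
from .genoqc import Grm, SnpPanel
from .varcomp import FixedEffectsDesign


@dataclass
class PedigreeStructure:
    """Half-sib families plus unrelated individuals."""

    n_sires: int
    offspring_per_sire: int
    n_unrelated: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sires, self.offspring_per_sire, self.n_unrelated) < 0:
            raise ValueError("pedigree counts must be non-negative")
        if self.n_total == 0:
            raise ValueError("empty pedigree structure")

    @property
    def n_total(self) -> int:
        return self.n_sires * self.offspring_per_sire + self.n_unrelated


@dataclass
class SimTruth:
    """Ground truth carried alongside simulated traits and tables."""

    true_h2: float | None = None
    sigma_a2: float | None = None
    sigma_e2: float | None = None
    causal_snp_ids: list = field(default_factory=list)
    causal_betas: list = field(default_factory=list)
    basis_correlations: dict = field(default_factory=dict)
    fixed_effect_values: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_a2 is not None and self.sigma_e2 is not None:
            h2 = self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)
            if self.true_h2 is None:
                self.true_h2 = h2
            elif abs(self.true_h2 - h2) > 1e-12:
                raise ValueError("true_h2 inconsistent with variance components")
        for pair, rho in self.basis_correlations.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"basis correlation {rho} for {pair} outside [-1, 1]")


def simulate_genotypes(
    structure: PedigreeStructure,
    n_markers: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_chromosomes: int = 30,
    seed: int | None = None,
) -> SnpPanel:
    """Simulate a biallelic panel over a half-sib cohort.

    Per-marker allele frequencies are uniform on ``maf_range``; founders
    (sires, dams, unrelated) are Hardy-Weinberg draws; each offspring
    receives one gamete sampled from its sire's two haplotypes (markers
    independent) and one population gamete from an unrelated dam.
    """
    if n_markers < 1:
        raise ValueError("need at least one marker")
    lo, hi = maf_range
    if not (0.01 <= lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within [0.01, 0.5]")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_markers)

    # sire haplotypes: two Bernoulli(p) chromosomes each
    sire_h1 = (rng.random((structure.n_sires, n_markers)) < p).astype(np.int8)
    sire_h2 = (rng.random((structure.n_sires, n_markers)) < p).astype(np.int8)
    rows = []
    for s in range(structure.n_sires):
        for _ in range(structure.offspring_per_sire):
            pick = rng.random(n_markers) < 0.5
            paternal = np.where(pick, sire_h1[s], sire_h2[s])
            maternal = (rng.random(n_markers) < p).astype(np.int8)
            rows.append(paternal + maternal)
    if structure.n_unrelated:
        unrelated = (rng.random((structure.n_unrelated, n_markers)) < p).astype(np.int8) \
            + (rng.random((structure.n_unrelated, n_markers)) < p).astype(np.int8)
        rows.extend(unrelated)
    dosages = np.asarray(rows, dtype=float)

    width = len(str(n_markers))
    marker_ids = [f"snp{k + 1:0{width}d}" for k in range(n_markers)]
    chrom = np.arange(n_markers) % n_chromosomes + 1
    order = np.argsort(chrom, kind="stable")
    chrom = chrom[order]
    dosages = dosages[:, order]
    marker_ids = [marker_ids[i] for i in order]
    pos = np.empty(n_markers, dtype=int)
    for c in range(1, n_chromosomes + 1):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = np.sort(rng.integers(1, 100_000_000, size=len(idx)))
    markers = pd.DataFrame({"chrom": chrom, "pos": pos, "a1": "A", "a2": "B"},
                           index=pd.Index(marker_ids, name="marker"))
    n_off = structure.n_sires * structure.offspring_per_sire
    sample_ids = [f"off{i + 1:04d}" for i in range(n_off)] + \
                 [f"unr{i + 1:04d}" for i in range(structure.n_unrelated)]
    return SnpPanel(markers, dosages, sample_ids)


def _mvn_from_grm(grm: Grm, sigma_a2: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a ~ N(0, sigma_a2 G) via symmetric factorization.

    Small negative eigenvalues (finite-marker artifacts) are clipped at 0;
    a genuinely non-PSD matrix raises.
    """
    d, u = linalg.eigh(grm.g)
    if d[0] < -1e-6 * max(d[-1], 1.0):
        raise ValueError("GRM not positive semi-definite within tolerance")
    d = np.clip(d, 0.0, None)
    z = rng.standard_normal(len(d))
    return u @ (np.sqrt(sigma_a2 * d) * z)


def simulate_polygenic_trait(
    grm: Grm,
    design: FixedEffectsDesign,
    truth: SimTruth,
    seed: int | None = None,
) -> TraitVector:
    """Simulate y = X beta + a + e under the animal model.

    Fixed effects come from ``truth.fixed_effect_values`` keyed by design
    column name (absent columns get effect 0).
    """
    if truth.sigma_a2 is None or truth.sigma_e2 is None:
        raise ValueError("truth must set sigma_a2 and sigma_e2")
    if truth.sigma_a2 < 0 or truth.sigma_e2 <= 0:
        raise ValueError("need sigma_a2 >= 0 and sigma_e2 > 0")
    if list(design.sample_ids) != list(grm.sample_ids):
        raise ValueError("design and GRM sample ids must align")
    rng = np.random.default_rng(seed)
    beta = np.array([truth.fixed_effect_values.get(c, 0.0) for c in design.column_names])
    fixed = design.x @ beta
    a = _mvn_from_grm(grm, truth.sigma_a2, rng) if truth.sigma_a2 > 0 else np.zeros(len(fixed))
    e = rng.standard_normal(len(fixed)) * np.sqrt(truth.sigma_e2)
    tv = TraitVector(pd.Series(fixed + a + e, index=design.sample_ids), name="sim_polygenic")
    tv.transform_log.append({"transform": "simulated", "truth": truth})
    return tv


def simulate_qtl_trait(
    panel: SnpPanel,
    grm: Grm,
    causal_snp: str,
    variance_fraction: float,
    truth: SimTruth,
    seed: int | None = None,
    design: FixedEffectsDesign | None = None,
) -> TraitVector:
    """Polygenic trait plus one causal marker of given variance share.

    The allele-substitution effect is scaled so the (centered) marker
    explains ``variance_fraction`` of total trait variance in expectation:
    beta^2 var(g) = f/(1-f) * (sigma_a2 + sigma_e2).
    """
    if not 0.0 <= variance_fraction < 1.0:
        raise ValueError("variance_fraction must be in [0, 1)")
    if causal_snp not in panel.markers.index:
        raise KeyError(f"causal marker {causal_snp!r} not in panel")
    if design is None:
        design = FixedEffectsDesign(panel.sample_ids,
                                    np.ones((panel.n_samples, 1)), ["intercept"])
    base = simulate_polygenic_trait(grm, design, truth, seed=seed)
    if variance_fraction == 0.0:
        return base
    j = panel.markers.index.get_loc(causal_snp)
    g = panel.dosages[:, j]
    var_g = float(np.var(g))
    if var_g == 0.0:
        raise ValueError(f"causal marker {causal_snp!r} is monomorphic")
    total = truth.sigma_a2 + truth.sigma_e2
    beta = np.sqrt(variance_fraction / (1.0 - variance_fraction) * total / var_g)
    sign = truth.causal_betas[0] if truth.causal_betas else 1.0
    beta *= np.sign(sign) if sign != 0 else 1.0
    values = base.values + pd.Series(beta * (g - g.mean()), index=panel.sample_ids)
    truth.causal_snp_ids = [causal_snp]
    truth.causal_betas = [float(beta)]
    tv = TraitVector(values, name="sim_qtl")
    tv.transform_log.append({"transform": "simulated", "truth": truth})
    return tv


def simulate_count_table(
    n_samples: int,
    n_taxa: int,
    depth: int,
    basis_correlations: dict | None = None,
    seed: int | None = None,
    model: str = "lognormal",
    log_mean_sd: float = 1.0,
    dm_overdispersion: float = 100.0,
) -> tuple[TaxonCountTable, SimTruth]:
    """Compositional counts with a known latent correlation structure.

    Latent basis abundances are log-normal: log-basis ~ MVN(mu, C) with C
    the requested correlation matrix (identity plus planted pairs) and mu
    per-taxon base means drawn N(0, log_mean_sd^2) to give realistically
    uneven compositions.  Counts are multinomial draws at ``depth`` per
    sample (every row sums to ``depth`` exactly); ``model='dirichlet'``
    adds Dirichlet-multinomial overdispersion instead.
    """
    if n_taxa < 10:
        raise ValueError("need >= 10 taxa (sparsity assumption downstream)")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    basis_correlations = basis_correlations or {}
    corr = np.eye(n_taxa)
    for (i, j), rho in basis_correlations.items():
        corr[i, j] = corr[j, i] = rho
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("requested basis correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, log_mean_sd, size=n_taxa)
    z = rng.standard_normal((n_samples, n_taxa)) @ chol.T
    basis = np.exp(mu + z)
    frac = basis / basis.sum(axis=1, keepdims=True)
    if model == "lognormal":
        counts = np.stack([rng.multinomial(depth, f) for f in frac])
    elif model == "dirichlet":
        alpha = frac * dm_overdispersion
        probs = np.stack([rng.dirichlet(a) for a in alpha])
        counts = np.stack([rng.multinomial(depth, f) for f in probs])
    else:
        raise ValueError(f"unknown compositional model {model!r}")
    samples = [f"s{i + 1:04d}" for i in range(n_samples)]
    taxa = [f"taxon{j + 1:03d}" for j in range(n_taxa)]
    table = TaxonCountTable(pd.DataFrame(counts, index=samples, columns=taxa))
    truth = SimTruth(basis_correlations={(taxa[i], taxa[j]): rho
                                         for (i, j), rho in basis_correlations.items()},
                     seed=seed)
    return table, truth


def simulate_metadata(
    sample_ids,
    n_breeds: int = 3,
    n_sexes: int = 3,
    n_diets: int = 4,
    age_mean: float = 293.0,
    age_sd: float = 15.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Breed/sex/diet factors and an age covariate for a cohort.

    Diet is assigned within sex classes (as in commercial feedlots, where
    ration follows sex and growth stage) but not perfectly confounded.
    """
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    breeds = [f"B{i + 1}" for i in range(n_breeds)]
    sexes = [f"S{i + 1}" for i in range(n_sexes)]
    diets = [f"D{i + 1}" for i in range(n_diets)]
    meta = pd.DataFrame({
        "breed": rng.choice(breeds, size=n),
        "sex": rng.choice(sexes, size=n),
        "diet": rng.choice(diets, size=n),
        "age": np.round(rng.normal(age_mean, age_sd, size=n)),
    }, index=pd.Index(sample_ids, name="sample"))
    return meta
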