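"""End-to-end pipeline driver with run provenance.

Chains the full analysis on provided inputs: detected-taxon filtering ->
rarefaction -> alpha/beta diversity and PCoA -> trait construction
(log10 relative abundance, outlier removal) -> SNP QC -> GRM -> REML
heritability per feature -> mixed-model GWAS for eligible features ->
SparCC co-occurrence network -> Spearman screen of heritable features
against host traits.  Every stage logs its parameters and output hashes
into a :class:`RunManifest`; stochastic stages consume child seeds
derived deterministically from the global seed.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diversity, features, genoqc, gwas, io, pheno_assoc, sparcc_net, varcomp

# fixed stage order gives each stochastic stage a stable child seed
_STAGES = ("rarefy_alpha", "rarefy_beta", "network_subsample", "sparcc",
           "sparcc_pvalues", "permanova")

HOST_TRAIT_COLUMNS = ("DMI", "ADG", "MWT", "backfat", "FCR", "RFI", "RFIf",
                      "acetate", "propionate", "butyrate")


@dataclass
class RunConfig:
    """Validated parameters for one pipeline run."""

    counts_path: str
    metadata_path: str
    dosage_path: str
    map_path: str
    out_dir: str
    lineage_path: str | None = None
    rank: str | None = None
    min_max_relabund: float = 0.005
    min_prevalence: float = 0.2
    depth: int = 2000
    rarefaction_iterations: int = 100
    hwe_p_min: float = 1e-6
    maf_min: float = 0.05
    callrate_min: float = 0.90
    formula: str = "breed+sex+diet+age"
    h2_heritable: float = 0.15
    h2_gwas_eligible: float = 0.1
    fdr_significant: float = 0.1
    fdr_suggestive: float = 0.2
    sparcc_permutations: int = 10000
    sparcc_r_threshold: float = 0.3
    sparcc_p_threshold: float = 0.001
    n_pcoa_axes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (("min_max_relabund", 0, 1), ("min_prevalence", 0, 1),
                             ("maf_min", 0, 0.5), ("callrate_min", 0, 1),
                             ("h2_heritable", 0, 1), ("h2_gwas_eligible", 0, 1),
                             ("fdr_significant", 0, 1), ("fdr_suggestive", 0, 1),
                             ("sparcc_p_threshold", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"config {name}={v} outside [{lo}, {hi}]")
        if self.depth < 1 or self.rarefaction_iterations < 1 or self.sparcc_permutations < 1:
            raise ValueError("depth, iterations and permutations must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat key=value config file (``#`` comments allowed)."""
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            typ = cls.__dataclass_fields__[key].type
            if value.lower() in ("none", ""):
                kwargs[key] = None
            elif "int" in str(typ):
                kwargs[key] = int(value)
            elif "float" in str(typ):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def child_seed(self, stage: str) -> int:
        return int(np.random.SeedSequence([self.seed, _STAGES.index(stage)])
                   .generate_state(1)[0] % 2**31)


@dataclass
class RunManifest:
    """Per-stage provenance: parameters, outputs, hashes, wall-clock."""

    version: str = __version__
    seed: int | None = None
    stages: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def record(self, stage: str, params: dict, outputs: list, t0: float) -> None:
        self.stages[stage] = {
            "params": params,
            "outputs": {str(p): _sha256(p) for p in outputs},
            "wall_clock_s": round(time.monotonic() - t0, 3),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    def output_hashes(self) -> dict:
        return {name: stage["outputs"] for name, stage in self.stages.items()}


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full chain and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)
    stage = "load"
    try:
        t0 = time.monotonic()
        table = io.read_count_table(config.counts_path, config.lineage_path)
        metadata = io.read_metadata(config.metadata_path)
        panel = io.read_dosage_tsv(config.dosage_path, config.map_path)
        manifest.record(stage, {"counts": config.counts_path}, [], t0)

        # -- community features ------------------------------------------
        stage = "filter"
        t0 = time.monotonic()
        if config.rank is not None:
            table = features.collapse_to_rank(table, config.rank)
        detected = features.filter_detected_taxa(
            table, config.min_max_relabund, config.min_prevalence)
        manifest.record(stage, {"rank": config.rank,
                                "taxa_in": len(table.taxon_ids),
                                "taxa_out": len(detected.taxon_ids)}, [], t0)

        stage = "diversity"
        t0 = time.monotonic()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alpha = diversity.rarefied_alpha(
                detected, config.depth, config.rarefaction_iterations,
                seed=config.child_seed("rarefy_alpha"))
            beta_tables, _ = features.rarefy(
                detected, config.depth, iterations=1,
                seed=config.child_seed("rarefy_beta"))
        dist = diversity.bray_curtis(beta_tables[0])
        coords = diversity.pcoa(dist, n_axes=config.n_pcoa_axes)
        alpha_path = out / "alpha_diversity.tsv"
        io.write_traits(alpha, alpha_path, seed=config.seed)
        pcoa_path = out / "pcoa_axes.tsv"
        io.write_traits(coords.coordinates, pcoa_path, seed=config.seed)
        manifest.record(stage, {"depth": config.depth,
                                "iterations": config.rarefaction_iterations},
                        [alpha_path, pcoa_path], t0)

        stage = "traits"
        t0 = time.monotonic()
        rel = features.relative_abundance(detected)
        traits: dict[str, features.TraitVector] = {}
        for taxon in rel.columns:
            tv = features.log10_trait(rel[taxon], zero_policy="missing", name=str(taxon))
            traits[str(taxon)] = features.remove_outliers(tv)
        for col in alpha.columns:
            traits[str(col)] = features.remove_outliers(
                features.TraitVector(alpha[col], name=str(col)))
        for col in coords.coordinates.columns:
            traits[str(col)] = features.remove_outliers(
                features.TraitVector(coords.coordinates[col], name=str(col)))
        manifest.record(stage, {"n_traits": len(traits)}, [], t0)

        # -- genetics -----------------------------------------------------
        stage = "genoqc"
        t0 = time.monotonic()
        qc_panel, report = genoqc.qc_snps(panel, config.hwe_p_min,
                                          config.maf_min, config.callrate_min)
        qc_panel = genoqc.impute_missing(qc_panel)
        report_path = out / "snp_removal_report.tsv"
        io._write_tsv(report, report_path, seed=config.seed, index=False)
        grm = genoqc.build_grm(qc_panel)
        grm_path = out / "grm.tsv"
        io.write_grm(grm, grm_path, seed=config.seed)
        manifest.record(stage, {"markers_in": panel.n_markers,
                                "markers_out": qc_panel.n_markers}, [report_path, grm_path], t0)

        stage = "heritability"
        t0 = time.monotonic()
        design = varcomp.build_design(metadata, config.formula)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = varcomp.fit_many(traits, design, grm)
        fits["heritable"] = fits["converged"].fillna(False).astype(bool) & \
            (fits["h2"] >= config.h2_heritable)
        h2_path = out / "heritability.tsv"
        io._write_tsv(fits, h2_path, seed=config.seed, index_label="feature")
        manifest.record(stage, {"formula": config.formula,
                                "n_heritable": int(fits["heritable"].sum())}, [h2_path], t0)

        stage = "gwas"
        t0 = time.monotonic()
        qc_mapped = qc_panel
        eligible = fits.index[fits["converged"].fillna(False).astype(bool)
                              & (fits["h2"] >= config.h2_gwas_eligible)]
        assoc_frames = []
        for feat in eligible:
            adjusted = gwas.adjust_phenotype(traits[feat], design)
            scan = gwas.mixed_model_scan(adjusted, qc_mapped, grm)
            scan.insert(0, "taxon", feat)
            assoc_frames.append(scan)
        assoc = pd.concat(assoc_frames, ignore_index=True) if assoc_frames else \
            pd.DataFrame(columns=["taxon", "marker_id", "chromosome", "position",
                                  "beta", "se_beta", "p_value", "monomorphic",
                                  "fdr", "tier"])
        gwas_path = out / "associations.tsv"
        io._write_tsv(assoc, gwas_path, seed=config.seed, index=False)
        manifest.record(stage, {"n_eligible": len(eligible),
                                "n_significant": int((assoc["tier"] == "significant").sum())
                                if len(assoc) else 0}, [gwas_path], t0)

        stage = "network"
        t0 = time.monotonic()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net_table = sparcc_net.prefilter_for_network(
                detected, config.depth, config.min_prevalence,
                seed=config.child_seed("network_subsample"))
            observed = sparcc_net.sparcc_correlations(
                net_table, seed=config.child_seed("sparcc"))
            withp = sparcc_net.sparcc_pvalues(
                net_table, observed, permutations=config.sparcc_permutations,
                seed=config.child_seed("sparcc_pvalues"))
        edges = sparcc_net.build_network(withp, config.sparcc_r_threshold,
                                         config.sparcc_p_threshold)
        edge_df = pd.DataFrame([{"source": e.taxon_a, "target": e.taxon_b,
                                 "r": e.r, "p": e.p, "sign": e.sign} for e in edges],
                               columns=["source", "target", "r", "p", "sign"])
        edges_path = out / "network_edges.tsv"
        io._write_tsv(edge_df, edges_path, seed=config.seed, index=False)
        manifest.record(stage, {"permutations": config.sparcc_permutations,
                                "n_edges": len(edges)}, [edges_path], t0)

        stage = "correlation_screen"
        t0 = time.monotonic()
        heritable = pheno_assoc.select_heritable_features(
            fits[["h2", "converged"]].assign(converged=fits["converged"].fillna(False)),
            config.h2_heritable)
        host = pheno_assoc.derive_host_traits(metadata) \
            if {"DMI", "ADG"}.issubset(metadata.columns) else metadata
        host_cols = [c for c in HOST_TRAIT_COLUMNS if c in host.columns]
        if heritable and host_cols:
            feat_df = pd.DataFrame({f: traits[f].values for f in heritable})
            screen = pheno_assoc.spearman_screen(feat_df, host[host_cols])
            screen_df = screen.long_format()
        else:
            screen_df = pd.DataFrame(columns=["feature", "trait", "rho", "p", "n", "significant"])
        screen_path = out / "correlation_screen.tsv"
        io._write_tsv(screen_df, screen_path, seed=config.seed, index=False)
        manifest.record(stage, {"n_heritable": len(heritable),
                                "host_traits": host_cols}, [screen_path], t0)
    except Exception as exc:  # noqa: BLE001 - abort carries the stage name
        manifest.failed_stage = stage
        manifest.write(out / "manifest.FAILED.json")
        raise StageFailure(stage, exc) from exc

    manifest.write(out / "manifest.json")
    return manifest
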