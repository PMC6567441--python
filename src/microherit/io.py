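"""Plain-text readers and writers for the pipeline's objects.

TSV is the lingua franca; genotype panels additionally round-trip through
PLINK-style text (.ped/.map).  Every writer emits a comment header line
recording package version, seed and a digest of the parameters that
produced the file, and every reader skips comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import TaxonCountTable, TraitVector
from .genoqc import Grm, SnpPanel
from .synthdata import SimTruth


def _header(seed=None, params: dict | None = None) -> str:
    digest = hashlib.sha256(json.dumps(params or {}, sort_keys=True, default=str)
                            .encode()).hexdigest()[:12]
    return f"# microherit={__version__} seed={seed} params={digest}\n"


def _write_tsv(df: pd.DataFrame, path, seed=None, params=None, index_label=None,
               index: bool = True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(seed, params))
        df.to_csv(fh, sep="\t", index_label=index_label, index=index)


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# -- count tables -----------------------------------------------------------

def write_count_table(table: TaxonCountTable, path, lineage_path=None, seed=None) -> None:
    _write_tsv(table.counts, path, seed=seed, index_label="sample")
    if lineage_path is not None and table.lineage is not None:
        _write_tsv(table.lineage, lineage_path, seed=seed, index_label="taxon")


def read_count_table(path, lineage_path=None) -> TaxonCountTable:
    counts = _read_tsv(path, index_col=0)
    counts.index.name = None
    counts.columns.name = None
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative counts in count table")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("fractional counts in count table")
    lineage = _read_tsv(lineage_path, index_col=0, dtype=str).fillna("") \
        if lineage_path is not None else None
    if lineage is not None:
        missing = [t for t in counts.columns if t not in lineage.index]
        if missing:
            import warnings

            warnings.warn(f"{len(missing)} taxa without lineage; rank collapse will refuse them")
    return TaxonCountTable(counts, lineage)


# -- traits and metadata ----------------------------------------------------

def write_traits(traits: pd.DataFrame, path, seed=None) -> None:
    _write_tsv(traits, path, seed=seed, index_label="sample")


def read_traits(path) -> pd.DataFrame:
    return _read_tsv(path, index_col=0)


def read_metadata(path) -> pd.DataFrame:
    return _read_tsv(path, index_col=0)


def write_trait_vector(trait: TraitVector, path, seed=None) -> None:
    _write_tsv(trait.values.to_frame(trait.name or "value"), path, seed=seed,
               params={"transform_log": trait.transform_log}, index_label="sample")


# -- genotype panels --------------------------------------------------------

def write_dosage_tsv(panel: SnpPanel, prefix, seed=None) -> tuple[Path, Path]:
    """Write a panel as <prefix>.dosages.tsv + <prefix>.map.tsv."""
    prefix = Path(prefix)
    dosage_path = prefix.with_suffix(".dosages.tsv")
    map_path = prefix.with_suffix(".map.tsv")
    df = pd.DataFrame(panel.dosages, index=panel.sample_ids, columns=panel.marker_ids)
    _write_tsv(df, dosage_path, seed=seed, index_label="sample")
    _write_tsv(panel.markers, map_path, seed=seed, index_label="marker")
    return dosage_path, map_path


def read_dosage_tsv(dosage_path, map_path) -> SnpPanel:
    df = _read_tsv(dosage_path, index_col=0)
    markers = _read_tsv(map_path, index_col=0)
    observed = df.to_numpy(dtype=float)
    finite = observed[~np.isnan(observed)]
    bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
    if bad.size:
        raise ValueError(f"dosage value {bad[0]} outside {{0,1,2,missing}}")
    if list(df.columns) != list(markers.index):
        markers = markers.loc[df.columns]
    return SnpPanel(markers, observed, list(df.index))


def write_plink_text(panel: SnpPanel, prefix) -> tuple[Path, Path]:
    """Write PLINK-style .ped/.map text (dosage counts the a2 allele)."""
    prefix = Path(prefix)
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for mid, row in panel.markers.iterrows():
            pos = int(row["pos"]) if pd.notna(row["pos"]) else 0
            chrom = row["chrom"] if pd.notna(row["chrom"]) else 0
            fh.write(f"{chrom}\t{mid}\t0\t{pos}\n")
    geno_map = {0.0: "{a1} {a1}", 1.0: "{a1} {a2}", 2.0: "{a2} {a2}"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            fields = [str(sid), str(sid), "0", "0", "0", "-9"]
            for k, (mid, row) in enumerate(panel.markers.iterrows()):
                d = panel.dosages[i, k]
                if np.isnan(d):
                    fields.append("0 0")
                else:
                    fields.append(geno_map[d].format(a1=row["a1"], a2=row["a2"]))
            fh.write("\t".join(fields) + "\n")
    return ped_path, map_path


def read_plink_text(prefix) -> SnpPanel:
    """Read .ped/.map text; '0 0' is missing, dosage counts the second
    allele in the alphabetic ordering of observed alleles per marker."""
    prefix = Path(prefix)
    map_rows = []
    with open(prefix.with_suffix(".map")) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed .map line {lineno}")
            map_rows.append({"marker": parts[1], "chrom": parts[0],
                             "pos": int(parts[3]) if parts[3] != "0" else np.nan})
    markers = pd.DataFrame(map_rows).set_index("marker")
    if markers.index.has_duplicates:
        dup = markers.index[markers.index.duplicated()][0]
        raise ValueError(f"duplicated marker id {dup!r} in .map")
    m = len(markers)
    sample_ids, allele_rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(f"malformed .ped line {lineno}: expected {6 + 2 * m} fields")
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows).reshape(len(sample_ids), m, 2)
    dosages = np.full((len(sample_ids), m), np.nan)
    a1_list, a2_list = [], []
    for k in range(m):
        col = alleles[:, k, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise ValueError(f"marker {markers.index[k]!r} has >2 alleles")
        a1 = observed[0] if observed else "A"
        a2 = observed[1] if len(observed) > 1 else a1
        a1_list.append(a1)
        a2_list.append(a2)
        called = (col != "0").all(axis=1)
        dosages[called, k] = (col[called] == a2).sum(axis=1) if a2 != a1 else 0.0
    markers["a1"], markers["a2"] = a1_list, a2_list
    try:
        markers["chrom"] = pd.to_numeric(markers["chrom"])
    except (ValueError, TypeError):
        pass  # non-numeric chromosome labels (e.g. "X") stay as strings
    return SnpPanel(markers[["chrom", "pos", "a1", "a2"]], dosages, sample_ids)


# -- GRM, truth sidecars ----------------------------------------------------

def write_grm(grm: Grm, path, seed=None) -> None:
    df = pd.DataFrame(grm.g, index=grm.sample_ids, columns=grm.sample_ids)
    _write_tsv(df, path, seed=seed, params={"n_markers": grm.n_markers_used},
               index_label="sample")


def read_grm(path) -> Grm:
    df = _read_tsv(path, index_col=0)
    return Grm(list(df.index), df.to_numpy(dtype=float), n_markers_used=0)


def write_sim_truth(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header(truth.seed))
        for key in ("true_h2", "sigma_a2", "sigma_e2", "seed"):
            val = getattr(truth, key)
            if val is not None:
                fh.write(f"{key}={val}\n")
        if truth.causal_snp_ids:
            fh.write("causal_snp_ids=" + ",".join(map(str, truth.causal_snp_ids)) + "\n")
            fh.write("causal_betas=" + ",".join(f"{b:.10g}" for b in truth.causal_betas) + "\n")
        for pair, rho in truth.basis_correlations.items():
            fh.write(f"basis_correlation[{pair[0]},{pair[1]}]={rho}\n")
        for level, eff in truth.fixed_effect_values.items():
            fh.write(f"fixed_effect[{level}]={eff}\n")
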