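"""Microbial feature engineering on taxon count tables.

Turns raw sample-by-taxon counts into analyzable community features: rank
collapsing along taxonomy lineages, detected-taxon filtering, relative
abundances, log10-transformed trait vectors with +/- k SD outlier removal,
and repeated rarefaction (subsampling without replacement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TaxonCountTable:
    """Samples x taxa integer counts with optional taxonomy lineages.

    ``counts`` is a DataFrame (index: sample ids, columns: taxon ids) of
    non-negative integers.  ``lineage`` (optional) is indexed by taxon id
    with one column per rank, ordered coarse to fine (phylum ... genus or
    species); empty strings mark unclassified levels.
    """

    counts: pd.DataFrame
    lineage: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("sample and taxon ids must be unique")
        vals = c.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        self.counts = c.astype(np.int64)
        if self.lineage is not None and self.lineage.index.has_duplicates:
            raise ValueError("duplicate taxa in lineage")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class TraitVector:
    """One per-sample feature with a record of applied transforms.

    ``values`` is a float Series indexed by sample id; NaN marks a missing
    record.  ``transform_log`` accumulates dicts describing each transform
    (log10 policy, outlier bounds, adjustment design, ...).
    """

    values: pd.Series
    transform_log: list = field(default_factory=list)
    name: str | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids in trait")
        self.values = self.values.astype(float)
        if self.name is None:
            self.name = self.values.name

    def dropna(self) -> pd.Series:
        return self.values.dropna()


def _rank_labels(lineage: pd.DataFrame, rank: str) -> pd.Series:
    """Label every taxon at `rank`, falling back to 'unclassified <parent>'."""
    ranks = list(lineage.columns)
    if rank not in ranks:
        raise ValueError(f"rank {rank!r} not in lineage ranks {ranks}")
    upto = ranks[: ranks.index(rank) + 1]
    labels = {}
    for taxon, row in lineage[upto].iterrows():
        names = [str(v).strip() for v in row.tolist()]
        if names and names[-1] not in ("", "nan", "None"):
            labels[taxon] = names[-1]
        else:
            parent = next((n for n in reversed(names[:-1]) if n not in ("", "nan", "None")), "")
            labels[taxon] = f"unclassified {parent}".strip()
    return pd.Series(labels)


def collapse_to_rank(table: TaxonCountTable, rank: str) -> TaxonCountTable:
    """Sum counts of taxa sharing the same label at ``rank``.

    Taxa unclassified at ``rank`` are pooled under ``"unclassified
    <nearest classified parent>"``.  Per-sample totals are conserved.
    """
    if table.lineage is None:
        raise ValueError("count table has no lineage; cannot collapse")
    missing = [t for t in table.taxon_ids if t not in table.lineage.index]
    if missing:
        raise ValueError(f"taxa without lineage: {missing[:5]}")
    labels = _rank_labels(table.lineage.loc[table.taxon_ids], rank)
    collapsed = table.counts.T.groupby(labels.reindex(table.taxon_ids)).sum().T
    # carry a lineage for the collapsed taxa (ranks up to the target rank)
    ranks = list(table.lineage.columns)
    upto = ranks[: ranks.index(rank) + 1]
    lin_rows = {}
    for taxon, label in labels.items():
        if label not in lin_rows:
            lin_rows[label] = table.lineage.loc[taxon, upto]
    new_lineage = pd.DataFrame(lin_rows).T
    new_lineage.columns = upto
    new_lineage[rank] = list(new_lineage.index)
    return TaxonCountTable(collapsed, new_lineage.loc[collapsed.columns])


def relative_abundance(table: TaxonCountTable) -> pd.DataFrame:
    """Row-normalize counts to fractions summing to 1 per sample."""
    totals = table.totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    return table.counts.div(totals, axis=0)


def filter_detected_taxa(
    table: TaxonCountTable,
    min_max_relabund: float = 0.005,
    min_prevalence: float = 0.2,
) -> TaxonCountTable:
    """Keep taxa detected by the joint abundance/prevalence rule.

    A taxon is retained iff its maximum per-sample relative abundance is
    strictly above ``min_max_relabund`` AND the fraction of samples where
    it is present (count > 0) is strictly above ``min_prevalence``.
    """
    rel = relative_abundance(table)
    keep = (rel.max(axis=0) > min_max_relabund) & ((table.counts > 0).mean(axis=0) > min_prevalence)
    kept = table.counts.loc[:, keep[keep].index]
    lineage = table.lineage.loc[kept.columns] if table.lineage is not None else None
    return TaxonCountTable(kept, lineage)


def log10_trait(values: pd.Series, zero_policy: str = "missing", name: str | None = None) -> TraitVector:
    """log10-transform non-negative abundances into a trait vector.

    ``zero_policy='missing'`` (default) turns zeros into missing records;
    ``'half-min'`` substitutes half the smallest positive value before
    taking logs.
    """
    v = pd.Series(values, dtype=float)
    if (v.dropna() < 0).any():
        raise ValueError("negative abundance cannot be log10-transformed")
    if zero_policy not in ("missing", "half-min"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    out = v.copy()
    positive = v[v > 0]
    if zero_policy == "half-min" and (v == 0).any():
        if positive.empty:
            raise ValueError("all values zero; half-min pseudocount undefined")
        out[v == 0] = positive.min() / 2.0
        out = np.log10(out)
    else:
        out = pd.Series(np.where(v > 0, np.log10(np.where(v > 0, v, 1.0)), np.nan), index=v.index)
    tv = TraitVector(pd.Series(out, index=v.index), name=name or getattr(values, "name", None))
    tv.transform_log.append({"transform": "log10", "zero_policy": zero_policy})
    return tv


def remove_outliers(trait: TraitVector, k: float = 3.0) -> TraitVector:
    """Set values outside mean +/- k*SD (single pass) to missing."""
    obs = trait.dropna()
    if len(obs) < 3:
        raise ValueError("need >= 3 non-missing values for outlier screening")
    mean, sd = float(obs.mean()), float(obs.std(ddof=1))
    lo, hi = mean - k * sd, mean + k * sd
    out = trait.values.where((trait.values >= lo) & (trait.values <= hi))
    tv = TraitVector(out, transform_log=list(trait.transform_log), name=trait.name)
    tv.transform_log.append({"transform": "outlier-removal", "k": k, "lower": lo, "upper": hi,
                             "n_removed": int(obs.size - out.notna().sum())})
    return tv


def rarefy(
    table: TaxonCountTable,
    depth: int,
    iterations: int = 100,
    seed: int | None = None,
) -> tuple[list[TaxonCountTable], list]:
    """Repeatedly subsample each sample to exactly ``depth`` reads.

    Samples with total count below ``depth`` are excluded (and listed).
    Subsampling is without replacement (multivariate hypergeometric), so
    every retained row of every iteration sums to ``depth`` exactly.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.totals()
    excluded = list(totals[totals < depth].index)
    kept = table.counts.loc[totals[totals >= depth].index]
    rng = np.random.default_rng(seed)
    out = []
    raw = kept.to_numpy()
    for _ in range(iterations):
        sub = np.stack([rng.multivariate_hypergeometric(row, depth) for row in raw]) \
            if len(raw) else np.empty((0, raw.shape[1] if raw.ndim == 2 else 0), dtype=np.int64)
        out.append(TaxonCountTable(pd.DataFrame(sub, index=kept.index, columns=kept.columns),
                                   table.lineage))
    if excluded:
        warnings.warn(f"{len(excluded)} sample(s) below depth {depth} excluded from rarefaction")
    return out, excluded
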