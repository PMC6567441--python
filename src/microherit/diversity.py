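"""Alpha diversity, Bray-Curtis ordination, and permutation MANOVA.

Alpha indices delegate to scikit-bio (bias-corrected Chao1, Shannon,
Simpson as 1 - dominance, Good's coverage).  Principal coordinates use
Gower double-centering with no negative-eigenvalue correction; explained
fractions are taken over the positive eigenvalues only.  PERMANOVA is
Anderson's pseudo-F with optional permutation strata (labels shuffled
only within strata), which the off-the-shelf implementations lack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as _alpha
from skbio.stats.distance import DistanceMatrix

from .features import TaxonCountTable


def _check_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("all-zero count vector")
    if (c < 0).any():
        raise ValueError("negative counts")
    return c


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    return float(_alpha.chao1(_check_counts(counts).astype(int), bias_corrected=True))


def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy of the count composition (base 2 by default)."""
    return float(_alpha.shannon(_check_counts(counts).astype(int), base=base))


def simpson(counts) -> float:
    """Simpson diversity 1 - sum p_i^2."""
    return float(_alpha.simpson(_check_counts(counts).astype(int)))


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N (F1 singletons, N total reads)."""
    return float(_alpha.goods_coverage(_check_counts(counts).astype(int)))


ALPHA_METRICS = {"chao1": chao1, "shannon": shannon, "simpson": simpson,
                 "goods_coverage": goods_coverage}


def alpha_diversity_table(table: TaxonCountTable, metrics=("chao1", "shannon", "simpson", "goods_coverage")) -> pd.DataFrame:
    """Per-sample alpha indices for a single count table."""
    rows = {m: table.counts.apply(lambda r: ALPHA_METRICS[m](r.to_numpy()), axis=1) for m in metrics}
    return pd.DataFrame(rows)


def rarefied_alpha(
    table: TaxonCountTable,
    depth: int,
    iterations: int = 100,
    metrics=("chao1", "shannon", "simpson", "goods_coverage"),
    seed: int | None = None,
) -> pd.DataFrame:
    """Alpha indices computed per rarefaction iteration and averaged.

    Samples below ``depth`` are dropped before subsampling.
    """
    from .features import rarefy

    tables, _ = rarefy(table, depth, iterations=iterations, seed=seed)
    acc = None
    for t in tables:
        a = alpha_diversity_table(t, metrics)
        acc = a if acc is None else acc + a
    return acc / len(tables)


def bray_curtis(table: TaxonCountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), pairwise."""
    totals = table.totals()
    if (totals == 0).any():
        raise ValueError(f"sample {totals[totals == 0].index[0]!r} has zero total count")
    d = squareform(pdist(table.counts.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(s) for s in table.sample_ids])


@dataclass
class PcoaResult:
    """Principal coordinates with eigenvalues and explained fractions."""

    coordinates: pd.DataFrame  # samples x axes, columns PCoA1..PCoAk
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray

    def axis(self, i: int) -> pd.Series:
        return self.coordinates.iloc[:, i]


def pcoa(dist: DistanceMatrix, n_axes: int = 5) -> PcoaResult:
    """Classical scaling (PCoA) of a distance matrix.

    Gower-centers ``-d^2/2``, eigendecomposes, and scales eigenvectors by
    the square roots of the positive eigenvalues.  Explained fractions are
    eigenvalue / sum of positive eigenvalues; negative eigenvalues are
    dropped (no Lingoes/Cailliez correction).
    """
    d = dist.data
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-8 * max(abs(evals[0]), 1.0)
    positive = evals > tol
    n_pos = int(positive.sum())
    if n_axes > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating from {n_axes} axes")
        n_axes = n_pos
    lam = evals[:n_axes]
    coords = evecs[:, :n_axes] * np.sqrt(lam)
    frac = evals[positive] / evals[positive].sum()
    cols = [f"PCoA{i + 1}" for i in range(n_axes)]
    return PcoaResult(pd.DataFrame(coords, index=list(dist.ids), columns=cols),
                      eigenvalues=lam, explained_fraction=frac[:n_axes])


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Anderson's pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if ss_within == 0.0:  # perfect separation
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    dist: DistanceMatrix,
    groups,
    permutations: int = 1000,
    strata=None,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutational MANOVA on a distance matrix.

    ``groups`` is a sequence or Series (aligned to ``dist.ids``) of group
    labels.  With ``strata``, labels are permuted only within each stratum.
    The p-value is ``(1 + #{F_perm >= F_obs}) / (1 + permutations)`` so the
    observed statistic is always part of the null set.
    """
    ids = list(dist.ids)
    if isinstance(groups, pd.Series):
        groups = groups.reindex(ids).to_numpy()
    else:
        groups = np.asarray(groups)
    if len(groups) != len(ids):
        raise ValueError("groups length does not match distance matrix")
    codes, levels = pd.factorize(groups)
    if len(levels) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if strata is not None:
        if isinstance(strata, pd.Series):
            strata = strata.reindex(ids).to_numpy()
        strata = np.asarray(strata)
        strata_codes, _ = pd.factorize(strata)
    d2 = dist.data**2
    f_obs = _pseudo_f(d2, codes, len(levels))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        perm = np.arange(len(codes))
        if strata is None:
            rng.shuffle(perm)
        else:
            for s in np.unique(strata_codes):
                idx = np.flatnonzero(strata_codes == s)
                perm[idx] = rng.permutation(idx)
        if _pseudo_f(d2, codes[perm], len(levels)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + permutations)
    return float(f_obs), float(p)
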