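"""SNP quality control and genomic relationship matrix construction.

Markers live in a :class:`SnpPanel` (marker map plus an ``n x m`` dosage
matrix with NaN for missing calls).  QC follows the standard panel criteria
(Hardy-Weinberg equilibrium, minor allele frequency, call rate); the
relationship matrix is VanRaden method 1,

    G = Z Z' / (2 * sum_k p_k (1 - p_k)),    Z = M - 2p,

with ``M`` the dosage matrix and ``p`` the observed allele frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MAP_COLUMNS = ("chrom", "pos", "a1", "a2")


@dataclass
class SnpPanel:
    """Biallelic SNP panel: marker map plus sample-by-marker dosages.

    Parameters
    ----------
    markers : pandas.DataFrame
        Indexed by marker id with columns ``chrom``, ``pos`` (base pairs;
        NaN when the map position is unknown), ``a1``, ``a2``.
    dosages : numpy.ndarray
        ``n_samples x n_markers`` float array with values in {0, 1, 2}
        (count of the ``a2`` allele) or NaN for missing calls.
    sample_ids : list of str
    """

    markers: pd.DataFrame
    dosages: np.ndarray
    sample_ids: list

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.markers.index.has_duplicates:
            raise ValueError("duplicated marker ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample ids")
        if self.dosages.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage value {bad!r} outside {{0,1,2,missing}}")

    @property
    def marker_ids(self) -> list:
        return list(self.markers.index)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_frequencies(self) -> np.ndarray:
        """Observed frequency of the counted (a2) allele per marker."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def subset_markers(self, marker_ids) -> "SnpPanel":
        idx = self.markers.index.get_indexer(marker_ids)
        if (idx < 0).any():
            missing = [m for m, i in zip(marker_ids, idx) if i < 0]
            raise KeyError(f"markers not in panel: {missing[:5]}")
        return SnpPanel(self.markers.loc[marker_ids].copy(), self.dosages[:, idx].copy(), self.sample_ids)

    def subset_samples(self, sample_ids) -> "SnpPanel":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return SnpPanel(self.markers.copy(), self.dosages[idx, :].copy(), list(sample_ids))


@dataclass
class Grm:
    """Genomic relationship matrix with construction provenance."""

    sample_ids: list
    g: np.ndarray
    n_markers_used: int
    allele_freqs: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.sample_ids = list(self.sample_ids)
        n = len(self.sample_ids)
        if self.g.shape != (n, n):
            raise ValueError("GRM shape does not match sample ids")
        if not np.allclose(self.g, self.g.T, atol=1e-10):
            raise ValueError("GRM not symmetric within 1e-10")

    def subset(self, sample_ids) -> "Grm":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.asarray([pos[s] for s in sample_ids])
        return Grm(list(sample_ids), self.g[np.ix_(idx, idx)], self.n_markers_used, self.allele_freqs)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """One-degree-of-freedom chi-square test of Hardy-Weinberg equilibrium.

    Expected genotype counts are computed at the observed allele frequency.
    A monomorphic marker has no testable departure: returns ``(0.0, 1.0)``.
    """
    n = n_AA + n_Aa + n_aa
    if n <= 0:
        raise ValueError("no observed genotypes")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def qc_snps(
    panel: SnpPanel,
    hwe_p_min: float = 1e-6,
    maf_min: float = 0.05,
    callrate_min: float = 0.90,
) -> tuple[SnpPanel, pd.DataFrame]:
    """Filter markers on HWE, MAF and call rate.

    Retains markers with HWE p > ``hwe_p_min``, MAF >= ``maf_min`` and call
    rate >= ``callrate_min``.  Returns the filtered panel and a removal
    report with one row per (marker, failed criterion).
    """
    if panel.n_markers == 0:
        raise ValueError("empty panel")
    d = panel.dosages
    call = panel.call_rates()
    freq = panel.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    # genotype counts per marker (AA = dosage 2 of the counted allele)
    n2 = np.nansum(d == 2.0, axis=0)
    n1 = np.nansum(d == 1.0, axis=0)
    n0 = np.nansum(d == 0.0, axis=0)
    rows = []
    keep = np.ones(panel.n_markers, dtype=bool)
    for k, mid in enumerate(panel.marker_ids):
        if call[k] == 0.0:
            keep[k] = False
            rows.append({"marker": mid, "criterion": "call rate", "value": 0.0})
            continue
        _, p_hwe = hwe_test(int(n2[k]), int(n1[k]), int(n0[k]))
        failed = False
        if p_hwe <= hwe_p_min:
            rows.append({"marker": mid, "criterion": "HWE", "value": p_hwe})
            failed = True
        if maf[k] < maf_min:
            rows.append({"marker": mid, "criterion": "MAF", "value": maf[k]})
            failed = True
        if call[k] < callrate_min:
            rows.append({"marker": mid, "criterion": "call rate", "value": call[k]})
            failed = True
        if failed:
            keep[k] = False
    report = pd.DataFrame(rows, columns=["marker", "criterion", "value"])
    kept = SnpPanel(panel.markers.loc[keep].copy(), panel.dosages[:, keep].copy(), panel.sample_ids)
    return kept, report


def impute_missing(panel: SnpPanel, method: str = "mean", seed: int | None = None) -> SnpPanel:
    """Fill missing dosages.

    ``mean``: missing -> 2 * observed allele frequency (deterministic;
    adequate at low missingness).  ``random``: draw from the observed
    genotype frequencies of the marker.
    """
    if method not in ("mean", "random"):
        raise ValueError(f"unknown imputation method {method!r}")
    d = panel.dosages.copy()
    miss = np.isnan(d)
    if not miss.any():
        return SnpPanel(panel.markers.copy(), d, panel.sample_ids)
    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        mid = panel.marker_ids[int(np.flatnonzero(fully_missing)[0])]
        raise ValueError(f"marker {mid!r} has no observed genotypes; cannot impute")
    if method == "mean":
        freq = panel.allele_frequencies()
        fill = np.broadcast_to(2.0 * freq, d.shape)
        d[miss] = fill[miss]
    else:
        rng = np.random.default_rng(seed)
        for k in np.flatnonzero(miss.any(axis=0)):
            obs = d[~miss[:, k], k]
            counts = np.array([(obs == g).sum() for g in (0.0, 1.0, 2.0)], dtype=float)
            probs = counts / counts.sum()
            d[miss[:, k], k] = rng.choice([0.0, 1.0, 2.0], size=int(miss[:, k].sum()), p=probs)
    return SnpPanel(panel.markers.copy(), d, panel.sample_ids)


def build_grm(panel: SnpPanel, allele_freqs: np.ndarray | None = None) -> Grm:
    """VanRaden method-1 genomic relationship matrix.

    ``allele_freqs`` defaults to the frequencies observed in the panel;
    external frequencies may be supplied (e.g. when the panel is a subset
    of the population the frequencies refer to).
    """
    if np.isnan(panel.dosages).any():
        raise ValueError("panel contains missing dosages; impute first")
    if allele_freqs is None:
        p = panel.allele_frequencies()
    else:
        p = np.asarray(allele_freqs, dtype=float)
        if p.shape != (panel.n_markers,):
            raise ValueError("allele_freqs length does not match marker count")
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ZeroDivisionError("all markers monomorphic: GRM denominator is zero")
    z = panel.dosages - 2.0 * p
    g = (z @ z.T) / denom
    g = (g + g.T) / 2.0  # enforce exact symmetry against rounding
    return Grm(panel.sample_ids, g, panel.n_markers, p)
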