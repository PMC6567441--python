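"""Compositional correlation inference (SparCC) and network construction.

SparCC estimates correlations between latent ("basis") abundances from
compositional counts.  For taxa i, j the log-ratio variance

    t_ij = var(log(x_i / x_j)) = omega_i + omega_j - 2 rho_ij sqrt(omega_i omega_j)

links observable variances to basis variances omega and correlations rho.
Under the sparsity assumption (most rho ~ 0) the row sums of t give a
linear system for omega; strongly correlated pairs violating sparsity are
iteratively excluded.  Correlations are aggregated by the median over
inner iterations of the fraction-estimation step.  Significance comes
from a permutation null where each taxon's counts are shuffled across
samples independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import TaxonCountTable, rarefy


@dataclass
class SparccResult:
    """Basis correlation matrix with optional permutation p-values."""

    taxon_ids: list
    r: np.ndarray
    p: np.ndarray | None = None
    n_exclusion_rounds_run: int = 0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.taxon_ids)
        if self.r.shape != (k, k):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("correlation matrix not symmetric")
        if np.abs(self.r).max() > 1 + 1e-9:
            raise ValueError("|r| exceeds 1")

    def r_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.taxon_ids, columns=self.taxon_ids)

    def p_frame(self) -> pd.DataFrame:
        if self.p is None:
            raise ValueError("p-values not computed")
        return pd.DataFrame(self.p, index=self.taxon_ids, columns=self.taxon_ids)


@dataclass
class NetworkEdge:
    """One co-occurrence edge surviving the |r| and p filters."""

    taxon_a: str
    taxon_b: str
    r: float
    p: float

    @property
    def sign(self) -> str:
        return "positive" if self.r > 0 else "negative"


def _log_fractions(counts: np.ndarray, mode: str, rng: np.random.Generator) -> np.ndarray:
    """Estimate log component fractions from counts.

    ``dirichlet``: posterior draw with an add-one prior (vectorized via
    gamma variates).  ``pseudocount``: deterministic (counts + 1) / total.
    """
    if mode == "dirichlet":
        gam = rng.standard_gamma(counts + 1.0)
        frac = gam / gam.sum(axis=1, keepdims=True)
    elif mode == "pseudocount":
        pseudo = counts + 1.0
        frac = pseudo / pseudo.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown pseudocount_mode {mode!r}")
    return np.log(frac)


def _solve_basis_variances(t: np.ndarray, included: np.ndarray) -> np.ndarray:
    """Solve the sparsity-approximation linear system for basis variances.

    ``included`` is a boolean pair-inclusion matrix (diagonal False).  The
    system is M omega = t_rowsums with M = diag(degree - 1) + A + I where
    A is the inclusion adjacency; for full inclusion of p taxa this is
    (p - 2) I + 11'.
    """
    deg = included.sum(axis=1).astype(float)
    m = np.diag(deg - 1.0) + included.astype(float) + np.eye(len(deg))
    rhs = (t * included).sum(axis=1)
    omega = np.linalg.solve(m, rhs)
    return np.clip(omega, 1e-12, None)


def _corr_from_t(t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    r = (omega[:, None] + omega[None, :] - t) / denom
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _sparcc_single(
    logx: np.ndarray,
    exclusion_threshold: float,
    max_exclusion_rounds: int,
) -> tuple[np.ndarray, int]:
    """One SparCC estimate from a matrix of log fractions."""
    p = logx.shape[1]
    cov = np.cov(logx, rowvar=False)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    included = ~np.eye(p, dtype=bool)
    rounds = 0
    omega = _solve_basis_variances(t, included)
    r = _corr_from_t(t, omega)
    for _ in range(max_exclusion_rounds):
        masked = np.abs(np.where(included, r, 0.0))
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        included[i, j] = included[j, i] = False
        if (included.sum(axis=1) < 3).any():  # keep the system well-posed
            included[i, j] = included[j, i] = True
            break
        rounds += 1
        omega = _solve_basis_variances(t, included)
        r = _corr_from_t(t, omega)
    return r, rounds


def sparcc_correlations(
    table: TaxonCountTable,
    inner_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
    pseudocount_mode: str = "dirichlet",
    seed: int | None = None,
) -> SparccResult:
    """Estimate basis correlations for every taxon pair.

    The fraction-estimation step is repeated ``inner_iterations`` times
    (each a Dirichlet posterior draw under the default mode) and the
    per-pair median is reported.  Deterministic ``pseudocount`` mode makes
    every iteration identical, so one suffices.
    """
    k = len(table.taxon_ids)
    if k < 4:
        raise ValueError("SparCC basis system underdetermined below 4 taxa")
    totals = table.totals()
    if (totals == 0).any():
        raise ValueError(f"sample {totals[totals == 0].index[0]!r} has zero total count")
    counts = table.counts.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    iters = 1 if pseudocount_mode == "pseudocount" else inner_iterations
    rs = np.empty((iters, k, k))
    rounds_max = 0
    for it in range(iters):
        logx = _log_fractions(counts, pseudocount_mode, rng)
        rs[it], rounds = _sparcc_single(logx, exclusion_threshold, max_exclusion_rounds)
        rounds_max = max(rounds_max, rounds)
    r = np.median(rs, axis=0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return SparccResult(list(table.taxon_ids), np.clip(r, -1, 1), None, rounds_max)


def sparcc_pvalues(
    table: TaxonCountTable,
    observed: SparccResult,
    permutations: int = 10000,
    seed: int | None = None,
    inner_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
    pseudocount_mode: str = "dirichlet",
) -> SparccResult:
    """Two-sided permutation p-values for observed SparCC correlations.

    Each permutation shuffles every taxon's counts across samples
    independently (margins preserved, all between-taxon association
    destroyed) and recomputes the correlations with the same settings.
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + permutations).
    """
    if permutations < 1:
        raise ValueError("need at least one permutation")
    if list(observed.taxon_ids) != list(table.taxon_ids):
        raise ValueError("observed result does not match table taxa")
    counts = table.counts.to_numpy(dtype=float)
    n, k = counts.shape
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(observed.r)
    exceed = np.zeros((k, k))
    for _ in range(permutations):
        perm = rng.permuted(counts, axis=0)  # each taxon shuffled independently
        perm_table = pd.DataFrame(perm, index=table.sample_ids, columns=table.taxon_ids)
        r_perm = sparcc_correlations(
            TaxonCountTable(perm_table, table.lineage),
            inner_iterations=inner_iterations,
            exclusion_threshold=exclusion_threshold,
            max_exclusion_rounds=max_exclusion_rounds,
            pseudocount_mode=pseudocount_mode,
            seed=int(rng.integers(2**31)),
        ).r
        exceed += np.abs(r_perm) >= abs_obs
    p = (1.0 + exceed) / (1.0 + permutations)
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 1.0 / (1.0 + permutations))
    return SparccResult(observed.taxon_ids, observed.r, p, observed.n_exclusion_rounds_run)


def build_network(
    result: SparccResult,
    r_threshold: float = 0.3,
    p_threshold: float = 0.001,
) -> list[NetworkEdge]:
    """Edges where |r| strictly exceeds ``r_threshold`` and p < ``p_threshold``."""
    if result.p is None:
        raise ValueError("p-values required to build the network")
    edges = []
    k = len(result.taxon_ids)
    for i in range(k):
        for j in range(i + 1, k):
            if abs(result.r[i, j]) > r_threshold and result.p[i, j] < p_threshold:
                edges.append(NetworkEdge(str(result.taxon_ids[i]), str(result.taxon_ids[j]),
                                         float(result.r[i, j]), float(result.p[i, j])))
    return edges


def prefilter_for_network(
    table: TaxonCountTable,
    depth: int,
    min_prevalence: float = 0.2,
    seed: int | None = None,
) -> TaxonCountTable:
    """Prevalence filter plus single seeded subsampling before SparCC.

    Samples under ``depth`` are removed; taxa present in fewer than
    ``min_prevalence`` of the retained samples are eliminated (taxa at
    exactly the threshold are kept); the remaining counts are subsampled
    once to ``depth``, so every output row sums to the depth exactly.
    """
    totals = table.totals()
    kept_samples = totals[totals >= depth].index
    counts = table.counts.loc[kept_samples]
    prevalence = (counts > 0).mean(axis=0)
    keep = prevalence[prevalence >= min_prevalence].index
    lineage = table.lineage.loc[keep] if table.lineage is not None else None
    filtered = TaxonCountTable(counts[keep], lineage)
    tables, _ = rarefy(filtered, depth, iterations=1, seed=seed)
    return tables[0]
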