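"""Genomic animal model: REML variance components and heritability.

The model is

    y = X b + a + e,    a ~ N(0, sigma_a^2 G),    e ~ N(0, sigma_e^2 I),

with G a genomic relationship matrix.  Narrow-sense heritability is
h2 = sigma_a^2 / (sigma_a^2 + sigma_e^2).

Estimation is REML by spectral decomposition (EMMA-style): eigendecompose
G once, rotate y and X into the eigenbasis, and profile the restricted
likelihood over the variance ratio lambda = sigma_a^2 / sigma_e^2 with a
log-spaced grid followed by bounded 1-D refinement.  With a single genetic
variance component this profile is exact, so the search is global.  The
standard error of h2 comes from the numerical curvature of the profile
restricted likelihood (delta method).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .features import TraitVector
from .genoqc import Grm

LAMBDA_BOUNDS = (1e-5, 1e5)
_GRID_SIZE = 50


@dataclass
class FixedEffectsDesign:
    """Reference-level-coded fixed-effect design matrix.

    Built by :func:`build_design`; rows align with ``sample_ids``.
    Aliased (rank-deficient) columns are dropped and recorded.
    """

    sample_ids: list
    x: np.ndarray
    column_names: list
    dropped_columns: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (len(self.sample_ids), len(self.column_names)):
            raise ValueError("design matrix shape mismatch")
        if np.linalg.matrix_rank(self.x) < self.x.shape[1]:
            raise ValueError("design matrix not full column rank")

    def subset(self, sample_ids) -> "FixedEffectsDesign":
        """Row-subset; re-checks rank and drops columns aliased in the subset."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        x = self.x[idx, :]
        keep, dropped = _independent_columns(x, self.column_names)
        return FixedEffectsDesign(list(sample_ids), x[:, keep],
                                  [self.column_names[j] for j in keep],
                                  self.dropped_columns + dropped)


def _independent_columns(x: np.ndarray, names) -> tuple[list, list]:
    """Greedy left-to-right selection of a full-rank column subset."""
    keep, dropped = [], []
    rank = 0
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > rank:
            keep.append(j)
            rank += 1
        else:
            dropped.append(names[j])
    return keep, dropped


def build_design(
    metadata: pd.DataFrame,
    formula: str = "breed+sex+diet+age",
    factors: tuple = ("breed", "sex", "diet"),
) -> FixedEffectsDesign:
    """Build an intercept + treatment-coded design from metadata columns.

    Terms in ``formula`` (separated by ``+``) that appear in ``factors``
    get reference-level dummy coding (first level alphabetically is the
    reference); other terms are numeric covariates.  Zero-variance
    covariates and columns aliased by nesting are dropped with a warning.
    """
    terms = [t.strip() for t in formula.split("+") if t.strip()]
    if metadata.empty:
        raise ValueError("empty metadata")
    for t in terms:
        if t not in metadata.columns:
            raise KeyError(f"formula term {t!r} not in metadata")
        if metadata[t].isna().any():
            raise ValueError(f"missing values in formula term {t!r}")
    cols, names = [np.ones(len(metadata))], ["intercept"]
    for t in terms:
        if t in factors:
            levels = sorted(pd.unique(metadata[t].astype(str)))
            for lev in levels[1:]:
                cols.append((metadata[t].astype(str) == lev).to_numpy(float))
                names.append(f"{t}[{lev}]")
        else:
            v = metadata[t].to_numpy(dtype=float)
            if np.ptp(v) == 0:
                warnings.warn(f"covariate {t!r} has zero variance; dropped")
                continue
            cols.append(v)
            names.append(t)
    x = np.column_stack(cols)
    keep, dropped = _independent_columns(x, names)
    if dropped:
        warnings.warn(f"aliased design columns dropped: {dropped}")
    return FixedEffectsDesign(list(metadata.index), x[:, keep],
                              [names[j] for j in keep], dropped)


@dataclass
class RemlFit:
    """REML estimates for one trait under the animal model."""

    sigma_a2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik_reml: float
    n_used: int
    converged: bool
    boundary: bool
    feature: str | None = None

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components out of range")
        expected = self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)
        if abs(self.h2 - expected) > 1e-10:
            raise ValueError("h2 inconsistent with variance components")


def heritability(sigma_a2: float, sigma_e2: float) -> float:
    """h2 = sigma_a2 / (sigma_a2 + sigma_e2)."""
    if sigma_a2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma_a2 + sigma_e2
    if total == 0:
        raise ValueError("both variance components zero; h2 undefined")
    return sigma_a2 / total


def classify_heritable(fit: RemlFit, threshold: float = 0.15) -> bool:
    """A feature counts as heritable iff h2 >= threshold (inclusive)."""
    if not fit.converged:
        raise ValueError("cannot classify an unconverged fit")
    return fit.h2 >= threshold


def _profile_reml(lam: float, d: np.ndarray, y_rot: np.ndarray, x_rot: np.ndarray,
                  logdet_xtx: float) -> tuple[float, float]:
    """Profile restricted log-likelihood at variance ratio lam.

    Returns (loglik, sigma_e2_hat).  All terms, including constants, are
    kept so the value equals a dense-matrix evaluation of the REML
    log-likelihood at (lam * sigma_e2_hat, sigma_e2_hat).
    """
    n, p = x_rot.shape
    w = 1.0 / (lam * d + 1.0)
    xtwx = x_rot.T @ (w[:, None] * x_rot)
    xtwy = x_rot.T @ (w * y_rot)
    beta = linalg.solve(xtwx, xtwy, assume_a="pos")
    resid = y_rot - x_rot @ beta
    ypy = float(np.sum(w * resid**2))
    sigma_e2 = ypy / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0 or sigma_e2 <= 0:
        return -np.inf, np.nan
    logdet_h = float(np.sum(np.log(lam * d + 1.0)))
    # equals the dense REML loglik: (n-p)ln(2*pi*s2) absorbs the n ln s2 from
    # ln|V| and the -p ln s2 from ln|X'V^-1 X|
    ll = -0.5 * ((n - p) * math.log(2.0 * math.pi * sigma_e2)
                 + logdet_h
                 + logdet_xtwx
                 - logdet_xtx
                 + (n - p))
    return ll, sigma_e2


def reml_loglik_dense(y: np.ndarray, x: np.ndarray, g: np.ndarray,
                      sigma_a2: float, sigma_e2: float) -> float:
    """Direct dense-matrix restricted log-likelihood (verification path).

    Evaluates the same quantity as the eigen-rotated profile without any
    rotation: V = sigma_a2 G + sigma_e2 I, beta-hat by GLS.
    """
    n, p = x.shape
    v = sigma_a2 * g + sigma_e2 * np.eye(n)
    vinv = linalg.inv(v)
    xtvx = x.T @ vinv @ x
    beta = linalg.solve(xtvx, x.T @ vinv @ y)
    r = y - x @ beta
    _, logdet_v = np.linalg.slogdet(v)
    _, logdet_xtvx = np.linalg.slogdet(xtvx)
    _, logdet_xtx = np.linalg.slogdet(x.T @ x)
    return float(-0.5 * ((n - p) * math.log(2.0 * math.pi)
                         + logdet_v + logdet_xtvx - logdet_xtx
                         + r @ vinv @ r))


def _align(trait: TraitVector, design: FixedEffectsDesign, grm: Grm):
    obs = trait.dropna()
    shared = [s for s in design.sample_ids if s in obs.index and s in set(grm.sample_ids)]
    y = obs.reindex(shared).to_numpy(dtype=float)
    return shared, y


def fit_animal_model(
    trait: TraitVector,
    design: FixedEffectsDesign,
    grm: Grm,
    min_n: int = 30,
    _eig: tuple | None = None,
) -> RemlFit:
    """REML fit of the genomic animal model for one trait.

    Samples missing in the trait, the design, or the GRM are dropped.
    ``_eig`` optionally supplies a precomputed eigendecomposition of the
    aligned GRM (``(values, vectors)``) so a batch of traits sharing the
    same sample set can reuse it.
    """
    shared, y = _align(trait, design, grm)
    if len(shared) < min_n:
        raise ValueError(f"only {len(shared)} usable samples (< {min_n})")
    des = design.subset(shared)
    x = des.x
    if _eig is None:
        g = grm.subset(shared).g
        d, u = linalg.eigh(g)
    else:
        d, u = _eig
    if d[0] < -1e-6 * max(d[-1], 1.0):
        raise ValueError("GRM not positive semi-definite within tolerance")
    d = np.clip(d, 0.0, None)
    if np.ptp(d) < 1e-8 * max(d[-1], 1.0):
        raise ValueError("GRM proportional to identity; variance components not identifiable")
    y_rot = u.T @ y
    x_rot = u.T @ x
    _, logdet_xtx = np.linalg.slogdet(x.T @ x)

    def neg_ll(log_lam: float) -> float:
        return -_profile_reml(math.exp(log_lam), d, y_rot, x_rot, logdet_xtx)[0]

    lo, hi = math.log(LAMBDA_BOUNDS[0]), math.log(LAMBDA_BOUNDS[1])
    grid = np.linspace(lo, hi, _GRID_SIZE)
    vals = np.array([neg_ll(gv) for gv in grid])
    j = int(np.argmin(vals))
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_ll, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-8})
    log_lam = float(res.x) if res.fun <= vals[j] else float(grid[j])
    lam = math.exp(log_lam)
    ll, sigma_e2 = _profile_reml(lam, d, y_rot, x_rot, logdet_xtx)

    boundary = log_lam <= lo + 1e-6 or log_lam >= hi - 1e-6
    if boundary and lam <= LAMBDA_BOUNDS[0] * (1 + 1e-6):
        # optimum pinned at h2 = 0: report the boundary model exactly
        ll0, sigma_e2_0 = _profile_reml(0.0, d, y_rot, x_rot, logdet_xtx)
        lam, ll, sigma_e2 = 0.0, ll0, sigma_e2_0
    sigma_a2 = lam * sigma_e2
    h2 = lam / (1.0 + lam)

    se_h2 = _se_from_curvature(h2, d, y_rot, x_rot, logdet_xtx)
    return RemlFit(sigma_a2=sigma_a2, sigma_e2=sigma_e2, h2=h2, se_h2=se_h2,
                   loglik_reml=ll, n_used=len(shared),
                   converged=bool(res.success or np.isfinite(ll)),
                   boundary=boundary, feature=trait.name)


def _se_from_curvature(h2: float, d, y_rot, x_rot, logdet_xtx, step: float = 1e-3) -> float:
    """Delta-method SE from the numerical curvature of the profile in h2."""

    def ll_of_h2(h: float) -> float:
        h = min(max(h, 0.0), 1.0 - 1e-12)
        lam = h / (1.0 - h)
        return _profile_reml(lam, d, y_rot, x_rot, logdet_xtx)[0]

    if h2 <= step or h2 >= 1.0 - step:  # boundary: curvature one-sided/undefined
        if h2 <= step:
            # forward second difference at the lower boundary
            f0, f1, f2 = ll_of_h2(h2), ll_of_h2(h2 + step), ll_of_h2(h2 + 2 * step)
            curv = (f2 - 2 * f1 + f0) / step**2
        else:
            f0, f1, f2 = ll_of_h2(h2), ll_of_h2(h2 - step), ll_of_h2(h2 - 2 * step)
            curv = (f2 - 2 * f1 + f0) / step**2
    else:
        f0, fp, fm = ll_of_h2(h2), ll_of_h2(h2 + step), ll_of_h2(h2 - step)
        curv = (fp - 2 * f0 + fm) / step**2
    if not np.isfinite(curv) or curv >= 0:
        return float("nan")
    return float(math.sqrt(-1.0 / curv))


def fit_many(
    traits: dict,
    design: FixedEffectsDesign,
    grm: Grm,
    min_n: int = 30,
) -> pd.DataFrame:
    """Fit the animal model for a batch of traits; one row per feature.

    Eigendecompositions are cached per distinct sample subset, since
    traits sharing a missingness pattern share the rotated basis.
    """
    cache: dict[tuple, tuple] = {}
    rows = []
    for name, trait in traits.items():
        try:
            shared, _ = _align(trait, design, grm)
            key = tuple(shared)
            if key not in cache and len(shared) >= min_n:
                cache[key] = tuple(linalg.eigh(grm.subset(list(key)).g))
            fit = fit_animal_model(trait, design, grm, min_n=min_n, _eig=cache.get(key))
            rows.append({"feature": name, "n_used": fit.n_used, "sigma_a2": fit.sigma_a2,
                         "sigma_e2": fit.sigma_e2, "h2": fit.h2, "se_h2": fit.se_h2,
                         "loglik_reml": fit.loglik_reml, "converged": fit.converged,
                         "boundary": fit.boundary})
        except ValueError as exc:
            rows.append({"feature": name, "n_used": 0, "sigma_a2": np.nan, "sigma_e2": np.nan,
                         "h2": np.nan, "se_h2": np.nan, "loglik_reml": np.nan,
                         "converged": False, "boundary": False, "error": str(exc)})
    return pd.DataFrame(rows).set_index("feature")
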