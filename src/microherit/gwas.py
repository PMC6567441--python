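"""Single-marker mixed-model association for microbial traits.

The scan follows a two-stage procedure: traits are first adjusted for
fixed effects (OLS residuals on breed/sex/diet/age), then each marker is
tested as a fixed effect in

    y* = mu + m g + a + e,    a ~ N(0, sigma_a^2 G),  e ~ N(0, sigma_e^2 I),

with genotypes coded -1/0/1 for aa/Aa/AA.  In the default P3D mode the
variance components are estimated once under the marker-free null and
reused for every marker (generalized least squares in the rotated
eigenbasis); "exact" mode re-profiles the variance ratio per marker.
P-values use the t distribution with n - 2 degrees of freedom (mean +
marker), and are converted to per-trait Benjamini-Hochberg FDRs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .features import TraitVector
from .genoqc import Grm, SnpPanel
from .varcomp import FixedEffectsDesign, RemlFit, _profile_reml, fit_animal_model


def adjust_phenotype(trait: TraitVector, design: FixedEffectsDesign) -> TraitVector:
    """OLS residuals of the trait on the fixed-effect design.

    Samples missing the trait stay missing; the residuals are orthogonal
    to every design column.
    """
    obs = trait.dropna()
    shared = [s for s in design.sample_ids if s in obs.index]
    sub = design.subset(shared)
    if sub.dropped_columns and set(sub.dropped_columns) - set(design.dropped_columns):
        newly = sorted(set(sub.dropped_columns) - set(design.dropped_columns))
        raise ValueError(f"design rank-deficient after subsetting; aliased columns: {newly}")
    y = obs.reindex(shared).to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(sub.x, y, rcond=None)
    resid = y - sub.x @ beta
    out = pd.Series(np.nan, index=trait.values.index, dtype=float)
    out[shared] = resid
    tv = TraitVector(out, transform_log=list(trait.transform_log), name=trait.name)
    tv.transform_log.append({"transform": "fixed-effect-adjustment",
                             "columns": list(sub.column_names)})
    return tv


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_association(fdr: float) -> str:
    """Tier an association by FDR: significant (<0.1), suggestive
    (0.1 < FDR < 0.2), otherwise none.  Boundaries are strict."""
    if not (0 < fdr <= 1):
        raise ValueError("FDR must be in (0, 1]")
    if fdr < 0.1:
        return "significant"
    if 0.1 < fdr < 0.2:
        return "suggestive"
    return "none"


def gwas_eligible(fit: RemlFit, threshold: float = 0.1) -> bool:
    """A trait enters the scan iff its h2 estimate >= threshold."""
    if not fit.converged:
        raise ValueError("cannot judge eligibility of an unconverged fit")
    return fit.h2 >= threshold


def mixed_model_scan(
    adjusted: TraitVector,
    panel: SnpPanel,
    grm: Grm,
    mode: str = "P3D",
    variance_components: tuple[float, float] | None = None,
    require_position: bool = True,
) -> pd.DataFrame:
    """Test every mapped marker for association with an adjusted trait.

    Returns a DataFrame (one row per marker, sorted by chromosome and
    position) with beta, se_beta, p_value, fdr, tier and a ``monomorphic``
    flag.  ``variance_components`` optionally fixes (sigma_a2, sigma_e2),
    e.g. ``(0, s2)`` reduces every test to plain OLS.
    """
    if mode not in ("P3D", "exact"):
        raise ValueError(f"unknown scan mode {mode!r}")
    if np.isnan(panel.dosages).any():
        raise ValueError("panel contains missing dosages; impute first")
    obs = adjusted.dropna()
    shared = [s for s in panel.sample_ids if s in obs.index and s in set(grm.sample_ids)]
    y = obs.reindex(shared).to_numpy(dtype=float)
    n = len(shared)
    if n < 3:
        raise ValueError("too few samples for association testing")
    sub_panel = panel.subset_samples(shared)
    markers = sub_panel.markers
    if require_position:
        mapped = markers["pos"].notna() & markers["chrom"].notna()
        sub_panel = sub_panel.subset_markers(list(markers.index[mapped]))
        markers = sub_panel.markers
    geno = sub_panel.dosages - 1.0  # -1/0/1 coding for aa/Aa/AA
    g = grm.subset(shared).g
    d, u = linalg.eigh(g)
    d = np.clip(d, 0.0, None)
    y_rot = u.T @ y
    ones_rot = u.T @ np.ones(n)
    geno_rot = u.T @ geno

    if variance_components is not None:
        sigma_a2, sigma_e2 = variance_components
        lam = sigma_a2 / sigma_e2
    else:
        x0 = FixedEffectsDesign(shared, np.ones((n, 1)), ["intercept"])
        null_trait = TraitVector(pd.Series(y, index=shared))
        null_fit = fit_animal_model(null_trait, x0, grm, min_n=3, _eig=(d, u))
        sigma_a2, sigma_e2 = null_fit.sigma_a2, null_fit.sigma_e2
        lam = sigma_a2 / sigma_e2 if sigma_e2 > 0 else 0.0

    mono = np.ptp(geno, axis=0) == 0
    if mode == "P3D":
        beta, se, pvals = _scan_p3d(lam, d, y_rot, ones_rot, geno_rot, n)
    else:
        beta, se, pvals = _scan_exact(d, y_rot, ones_rot, geno_rot, n)
    beta[mono], se[mono], pvals[mono] = 0.0, np.nan, 1.0

    out = pd.DataFrame({
        "marker_id": list(markers.index),
        "chromosome": markers["chrom"].to_numpy(),
        "position": markers["pos"].to_numpy(),
        "beta": beta, "se_beta": se, "p_value": pvals,
        "monomorphic": mono,
    })
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["tier"] = [classify_association(f) for f in out["fdr"]]
    out = out.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)
    return out


def _scan_p3d(lam, d, y_rot, ones_rot, geno_rot, n):
    """Vectorized GLS marker tests with fixed variance ratio."""
    w = 1.0 / (lam * d + 1.0)
    wy = w * y_rot
    w1 = w * ones_rot
    a11 = float(ones_rot @ w1)
    b1 = float(y_rot @ w1)
    yy = float(y_rot @ wy)
    a12 = ones_rot @ (w[:, None] * geno_rot)      # per-marker 1'W g
    a22 = np.einsum("ij,ij->j", geno_rot, w[:, None] * geno_rot)
    b2 = y_rot @ (w[:, None] * geno_rot)
    det = a11 * a22 - a12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta0 = (a22 * b1 - a12 * b2) / det
        beta1 = (a11 * b2 - a12 * b1) / det
        rss = yy - (beta0 * b1 + beta1 * b2)
        df = n - 2
        s2 = rss / df
        var_b1 = s2 * a11 / det
        se = np.sqrt(var_b1)
        t = beta1 / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(p), p, 1.0)
    return beta1, se, np.clip(p, np.finfo(float).tiny, 1.0)


def _scan_exact(d, y_rot, ones_rot, geno_rot, n):
    """Per-marker re-profiled variance ratio (slow; verification mode)."""
    m = geno_rot.shape[1]
    beta = np.zeros(m)
    se = np.zeros(m)
    pvals = np.ones(m)
    for j in range(m):
        x_rot = np.column_stack([ones_rot, geno_rot[:, j]])
        if np.ptp(geno_rot[:, j]) == 0:
            continue
        _, logdet_xtx = np.linalg.slogdet(x_rot.T @ x_rot)
        grid = np.logspace(-5, 5, 30)
        lls = [_profile_reml(l, d, y_rot, x_rot, logdet_xtx)[0] for l in grid]
        lam = grid[int(np.argmax(lls))]
        b_j, s_j, p_j = _scan_p3d(lam, d, y_rot, ones_rot, geno_rot[:, j:j + 1], n)
        beta[j], se[j], pvals[j] = b_j[0], s_j[0], p_j[0]
    return beta, se, pvals


def scan_trait(
    trait: TraitVector,
    design: FixedEffectsDesign,
    panel: SnpPanel,
    grm: Grm,
    mode: str = "P3D",
) -> pd.DataFrame:
    """Convenience wrapper: adjust for fixed effects, then scan."""
    adjusted = adjust_phenotype(trait, design)
    return mixed_model_scan(adjusted, panel, grm, mode=mode)
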