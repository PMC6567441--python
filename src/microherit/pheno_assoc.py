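"""Host feed-efficiency traits and correlation screens.

Derived host traits: feed conversion ratio FCR = DMI / ADG; residual feed
intake RFI as the residual of DMI regressed on ADG and metabolic weight
(MWT), optionally backfat-adjusted (RFIf).  Heritable microbial features
(h2 >= 0.15) are screened against these traits and VFA measures with
Spearman rank correlations (average ranks, t-approximation p-values,
pairwise-complete samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import TraitVector


def log_ratio_feature(x: pd.Series, y: pd.Series, name: str | None = None) -> TraitVector:
    """log10 of the elementwise ratio: log10(x) - log10(y) per sample.

    Non-positive inputs yield a missing value for that sample.
    """
    x, y = x.align(y, join="inner")
    bad = (x <= 0) | (y <= 0) | x.isna() | y.isna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} sample(s) with non-positive input set missing")
    values = pd.Series(np.nan, index=x.index, dtype=float)
    ok = ~bad
    values[ok] = np.log10(x[ok]) - np.log10(y[ok])
    tv = TraitVector(values, name=name)
    tv.transform_log.append({"transform": "log10-ratio"})
    return tv


def compute_fcr(dmi: pd.Series, adg: pd.Series) -> pd.Series:
    """Feed conversion ratio DMI / ADG; ADG <= 0 yields missing."""
    dmi, adg = dmi.align(adg, join="inner")
    bad = adg <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} sample(s) with ADG <= 0 set missing in FCR")
    out = dmi / adg.where(~bad)
    out.name = "FCR"
    return out


def compute_rfi(
    dmi: pd.Series,
    adg: pd.Series,
    mwt: pd.Series,
    backfat: pd.Series | None = None,
) -> pd.Series:
    """Residual feed intake: OLS residual of DMI on ADG and MWT.

    With ``backfat`` the regression additionally adjusts for backfat
    thickness (the backfat-adjusted variant, RFIf).  Residuals sum to
    zero and are orthogonal to the regressors.
    """
    frame = pd.DataFrame({"dmi": dmi, "adg": adg, "mwt": mwt})
    if backfat is not None:
        frame["backfat"] = backfat
    complete = frame.dropna()
    if len(complete) < 10:
        raise ValueError(f"only {len(complete)} complete records (< 10)")
    x = np.column_stack([np.ones(len(complete))] + [complete[c].to_numpy()
                                                    for c in frame.columns if c != "dmi"])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear regressors in RFI model")
    y = complete["dmi"].to_numpy()
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    out = pd.Series(np.nan, index=frame.index, dtype=float)
    out[complete.index] = resid
    out.name = "RFIf" if backfat is not None else "RFI"
    return out


def derive_host_traits(metadata: pd.DataFrame) -> pd.DataFrame:
    """Add FCR, RFI (and RFIf when backfat present) to a host trait table."""
    out = metadata.copy()
    if {"DMI", "ADG"}.issubset(out.columns):
        out["FCR"] = compute_fcr(out["DMI"], out["ADG"])
    if {"DMI", "ADG", "MWT"}.issubset(out.columns):
        out["RFI"] = compute_rfi(out["DMI"], out["ADG"], out["MWT"])
        if "backfat" in out.columns:
            out["RFIf"] = compute_rfi(out["DMI"], out["ADG"], out["MWT"], out["backfat"])
    return out


@dataclass
class CorrelationScreen:
    """Feature-by-trait Spearman coefficients with p-values."""

    rho: pd.DataFrame
    p_values: pd.DataFrame
    n: pd.DataFrame
    p_threshold: float = 0.05

    def significant(self) -> pd.DataFrame:
        return (self.p_values < self.p_threshold) & self.rho.notna()

    def long_format(self) -> pd.DataFrame:
        rows = []
        for f in self.rho.index:
            for t in self.rho.columns:
                rows.append({"feature": f, "trait": t, "rho": self.rho.loc[f, t],
                             "p": self.p_values.loc[f, t], "n": self.n.loc[f, t],
                             "significant": bool(self.p_values.loc[f, t] < self.p_threshold)
                             if np.isfinite(self.p_values.loc[f, t]) else False})
        return pd.DataFrame(rows)


def spearman_screen(
    features: pd.DataFrame,
    traits: pd.DataFrame,
    p_threshold: float = 0.05,
    min_n: int = 5,
) -> CorrelationScreen:
    """Spearman rank correlation of every feature against every trait.

    Pairwise-complete handling: each pair uses its shared non-missing
    samples; pairs with fewer than ``min_n`` or a constant member are
    reported as missing.
    """
    shared = features.index.intersection(traits.index)
    rho = pd.DataFrame(np.nan, index=features.columns, columns=traits.columns)
    pv = rho.copy()
    nn = rho.copy()
    for f in features.columns:
        fv = features.loc[shared, f]
        for t in traits.columns:
            tv = traits.loc[shared, t]
            ok = fv.notna() & tv.notna()
            nn.loc[f, t] = int(ok.sum())
            if ok.sum() < min_n:
                continue
            a, b = fv[ok], tv[ok]
            if a.nunique() < 2 or b.nunique() < 2:
                continue
            res = stats.spearmanr(a, b)
            rho.loc[f, t] = res.statistic
            pv.loc[f, t] = res.pvalue
    return CorrelationScreen(rho, pv, nn, p_threshold)


def select_heritable_features(fits: pd.DataFrame, threshold: float = 0.15) -> list:
    """Feature ids with converged h2 estimates at or above ``threshold``."""
    if fits.empty:
        return []
    ok = fits["converged"].fillna(False).astype(bool) & (fits["h2"] >= threshold)
    return list(fits.index[ok])
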