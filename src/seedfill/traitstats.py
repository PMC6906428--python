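"""Multi-environment statistics on the derived filling traits.

Works on a long-format trait table (one row per line x environment) holding
the twelve logistic-derived parameters.  With a single observation per
line x environment cell, the two-way method-of-moments ANOVA identifies the
genetic variance sigma_g^2 from the genotype mean square and treats the
genotype-by-environment interaction mean square as the error term delta^2
(G x E and measurement error are confounded under this design).  Broad-sense
heritability on an entry-mean basis is then

    H^2 = sigma_g^2 / (sigma_g^2 + delta^2 / e)

with e environments.  Per-line best linear unbiased predictions shrink
environment-adjusted line means toward the grand mean by the heritability
ratio lambda = sigma_g^2 / (sigma_g^2 + delta^2/e), which on a balanced
layout coincides with a genotype-random-intercept mixed model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "variance_components",
    "heritability",
    "cv_percent",
    "correlation_matrix",
    "blup",
    "pool_t_test",
    "trait_summary",
]

#: long-format trait table key columns
LINE_COL = "line_id"
ENV_COL = "environment"


@dataclass(frozen=True)
class VarianceComponents:
    """Method-of-moments variance components of one trait."""

    sigma2_g: float       # genetic variance
    sigma2_e_resid: float  # residual (GxE-confounded error) variance
    sigma2_env: float     # environment main-effect variance
    n_env: int
    n_lines: int
    grand_mean: float
    truncated: bool = False  # a negative moment estimate was clipped to 0


def _pivot(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    for col in (LINE_COL, ENV_COL, trait):
        if col not in table.columns:
            raise KeyError(f"trait table lacks required column {col!r}")
    if table.duplicated([LINE_COL, ENV_COL]).any():
        dup = table[table.duplicated([LINE_COL, ENV_COL])].iloc[0]
        raise ValueError(
            f"line {dup[LINE_COL]!r} duplicated within environment {dup[ENV_COL]!r}"
        )
    return table.pivot(index=LINE_COL, columns=ENV_COL, values=trait)


def variance_components(table: pd.DataFrame, trait: str) -> VarianceComponents:
    """Two-way ANOVA moment estimates for one trait.

    sigma_g^2 = (MS_genotype - MS_interaction) / e and
    delta^2 = MS_interaction: with one observation per cell the interaction
    mean square is the error term.  The environment component is estimated
    analogously.  Up to 20% missing cells are tolerated and imputed by
    additive line + environment effects; beyond that an error is raised.
    Negative moment estimates are truncated to zero and flagged.
    """
    wide = _pivot(table, trait)
    n, e = wide.shape
    if e < 2:
        raise ValueError("heritability requires >= 2 environments")
    miss = wide.isna()
    if miss.values.mean() > 0.20:
        raise ValueError(
            f"{miss.values.mean():.0%} of line x environment cells are missing "
            "(> 20%); the layout is too unbalanced for moment estimation"
        )
    y = wide.to_numpy(dtype=float)
    if miss.values.any():
        grand = np.nanmean(y)
        line_eff = np.nanmean(y, axis=1) - grand
        env_eff = np.nanmean(y, axis=0) - grand
        fill = grand + line_eff[:, None] + env_eff[None, :]
        y = np.where(np.isnan(y), fill, y)

    grand = y.mean()
    line_means = y.mean(axis=1)
    env_means = y.mean(axis=0)
    ms_g = e * np.sum((line_means - grand) ** 2) / (n - 1)
    ms_env = n * np.sum((env_means - grand) ** 2) / (e - 1)
    resid = y - line_means[:, None] - env_means[None, :] + grand
    ms_int = np.sum(resid**2) / ((n - 1) * (e - 1))

    s2g = (ms_g - ms_int) / e
    s2env = (ms_env - ms_int) / n
    truncated = bool(s2g < 0 or s2env < 0)
    return VarianceComponents(
        sigma2_g=max(s2g, 0.0),
        sigma2_e_resid=float(ms_int),
        sigma2_env=max(s2env, 0.0),
        n_env=e,
        n_lines=n,
        grand_mean=float(grand),
        truncated=truncated,
    )


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability H^2 = sigma_g^2 / (sigma_g^2 + delta^2/e).

    Returns NaN (with a warning) when both components vanish.
    """
    if vc.n_env < 2:
        raise ValueError("heritability undefined for a single environment")
    denom = vc.sigma2_g + vc.sigma2_e_resid / vc.n_env
    if denom <= 0:
        warnings.warn("all variance components are zero; H^2 undefined")
        return float("nan")
    return vc.sigma2_g / denom


def cv_percent(values) -> float:
    """Coefficient of variation, 100*sd/mean with the n-1 sd. Scale-invariant."""
    x = np.asarray(values, dtype=float)
    m = x.mean()
    if abs(m) < 1e-300:
        raise ValueError("coefficient of variation undefined for zero mean")
    return 100.0 * x.std(ddof=1) / m


def correlation_matrix(
    table: pd.DataFrame, traits: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p over trait columns.

    p-values come from the t transform t = r*sqrt((n-2)/(1-r^2)).  Columns
    with zero variance yield NaN entries (flagged by a warning).  The r
    matrix is symmetric with unit diagonal.
    """
    if traits is None:
        skip = (LINE_COL, ENV_COL, "r_squared", "converged")
        traits = [c for c in table.columns if c not in skip]
    X = table[traits].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need >= 3 complete pairs for a correlation")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance trait column(s); correlations set to NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(p, 0.0)
    p[np.isnan(r)] = np.nan
    return (
        pd.DataFrame(r, index=traits, columns=traits),
        pd.DataFrame(p, index=traits, columns=traits),
    )


def blup(table: pd.DataFrame, trait: str) -> pd.Series:
    """Per-line BLUP of ``trait`` across environments.

    Environment means are removed, then each line mean is shrunk toward the
    grand mean by lambda_i = sigma_g^2 / (sigma_g^2 + delta^2/e_i), where e_i
    is the number of environments in which the line was observed.  Under a
    balanced layout this equals the genotype-random mixed-model prediction.
    """
    vc = variance_components(table, trait)
    wide = _pivot(table, trait)
    y = wide.to_numpy(dtype=float)
    env_means = np.nanmean(y, axis=0)
    centred = y - env_means[None, :]
    line_dev = np.nanmean(centred, axis=1)
    e_i = (~np.isnan(y)).sum(axis=1).astype(float)
    denom = vc.sigma2_g + vc.sigma2_e_resid / np.maximum(e_i, 1.0)
    lam = np.where(denom > 0, vc.sigma2_g / np.where(denom > 0, denom, 1.0), 0.0)
    pred = vc.grand_mean + lam * line_dev
    return pd.Series(pred, index=wide.index, name=f"blup_{trait}")


def pool_t_test(values_pool1, values_pool2) -> tuple[float, float, float]:
    """Welch two-sample t-test (two-sided) between two pools of trait values.

    Returns (t, df, p).  Two constant pools with equal means give t=0, p=1.
    """
    a = np.asarray(values_pool1, dtype=float)
    b = np.asarray(values_pool2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each pool needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def trait_summary(table: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Per-trait mean, CV%, variance components and H^2 across environments."""
    if traits is None:
        skip = (LINE_COL, ENV_COL, "r_squared", "converged")
        traits = [c for c in table.columns if c not in skip]
    rows = []
    for trait in traits:
        vc = variance_components(table, trait)
        vals = table[trait].to_numpy(dtype=float)
        rows.append({
            "trait": trait,
            "mean": vals.mean(),
            "cv_percent": cv_percent(vals),
            "sigma2_g": vc.sigma2_g,
            "sigma2_resid": vc.sigma2_e_resid,
            "H2": heritability(vc),
        })
    return pd.DataFrame(rows).set_index("trait")
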