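"""Per-CpG age association with empirical-Bayes variance moderation.

Each probe's β values are regressed on donor age by ordinary least squares
(case deletion for missing β).  Residual variances are then shrunk toward a
common prior by the standard moderated-t construction: the per-probe sample
variances s²ᵢ (dᵢ residual degrees of freedom) are modeled as scaled-F draws
around a prior variance s₀² with d₀ prior degrees of freedom, the prior is
estimated by matching the moments of log s², and the posterior variance is
the precision-weighted blend

    s̃²ᵢ = (d₀ s₀² + dᵢ s²ᵢ) / (d₀ + dᵢ).

The moderated t statistic slopeᵢ / (s̃ᵢ · SEᵢ) is referred to a t
distribution with d₀ + dᵢ degrees of freedom and p-values are adjusted by
Benjamini–Hochberg.  Probes with adjusted q below a threshold (default 0.01)
are called age-associated; for visualization the top-k of those by
across-sample β variance are selected and row-standardized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .datasets import ValidationError

__all__ = [
    "fit_age_linear_models",
    "moderate_variances",
    "ModeratedVariances",
    "age_association",
    "bh_adjust",
    "select_age_probes",
    "zscore_rows",
]


def fit_age_linear_models(betas: pd.DataFrame, ages) -> pd.DataFrame:
    """Per-probe OLS of β on age.

    Parameters
    ----------
    betas : DataFrame, probes × samples.
    ages : sequence aligned with the sample axis.

    Returns a DataFrame indexed by probe with columns ``slope`` (β-units per
    year), ``intercept``, ``sigma2`` (residual variance, df = n_used − 2),
    ``df``, ``n_used`` and ``se_unscaled`` (the age-design factor
    sqrt(1/Sxx); slope standard error = s · se_unscaled).  Probes with fewer
    than 3 usable samples get NaN results.
    """
    ages = np.asarray(ages, dtype=float)
    if betas.shape[1] != len(ages):
        raise ValidationError("ages length does not match sample axis")
    if betas.shape[1] < 3:
        raise ValidationError("need at least 3 samples")
    if np.nanstd(ages) == 0:
        raise ValidationError("ages are constant; cannot fit an age model")

    B = betas.to_numpy(dtype=float)
    mask = ~np.isnan(B)
    Bz = np.where(mask, B, 0.0)
    n = mask.sum(axis=1).astype(float)
    sx = mask @ ages
    sxx = mask @ (ages**2)
    sy = Bz.sum(axis=1)
    sxy = Bz @ ages
    syy = (Bz**2).sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        sxx_c = sxx - sx**2 / n
        sxy_c = sxy - sx * sy / n
        syy_c = syy - sy**2 / n
        slope = sxy_c / sxx_c
        intercept = sy / n - slope * sx / n
        rss = np.maximum(syy_c - sxy_c**2 / sxx_c, 0.0)
        df = n - 2
        sigma2 = rss / df
        se_unscaled = np.sqrt(1.0 / sxx_c)

    unusable = (n < 3) | ~np.isfinite(sxx_c) | (sxx_c <= 0)
    for arr in (slope, intercept, sigma2, se_unscaled):
        arr[unusable] = np.nan
    df = np.where(unusable, np.nan, df)

    return pd.DataFrame(
        {
            "slope": slope,
            "intercept": intercept,
            "sigma2": sigma2,
            "df": df,
            "n_used": n,
            "se_unscaled": se_unscaled,
        },
        index=betas.index,
    )


@dataclass
class ModeratedVariances:
    d0: float          # prior degrees of freedom (np.inf = complete pooling)
    s02: float         # prior variance
    s2_post: np.ndarray  # posterior (moderated) variances, per probe


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on y: trigamma(y) = x (monotone decreasing)
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def moderate_variances(s2, df, d0: float | None = None, s02: float | None = None) -> ModeratedVariances:
    """Empirical-Bayes shrinkage of per-probe residual variances.

    When ``d0``/``s02`` are not supplied they are estimated by moment
    matching on log s²: with zᵢ = log s²ᵢ, E[zᵢ] = log s₀² + ψ(dᵢ/2) −
    log(dᵢ/2) − ψ(d₀/2) + log(d₀/2) and Var[zᵢ] = ψ′(dᵢ/2) + ψ′(d₀/2), so d₀
    solves a trigamma equation (Newton) and s₀² follows from the mean.
    Passing ``d0=0`` disables shrinkage (s̃² = s²); if the log-variance
    spread is no larger than expected from the χ² sampling noise alone, d₀ is
    infinite and every probe is pooled to s₀².
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    if np.any(s2[np.isfinite(s2)] < 0):
        raise ValidationError("negative residual variance")
    if d0 is not None and d0 == 0:
        return ModeratedVariances(d0=0.0, s02=float("nan"), s2_post=s2.copy())

    ok = np.isfinite(s2) & np.isfinite(df) & (df > 0) & (s2 > 0)
    if d0 is None or s02 is None:
        if not ok.any():
            warnings.warn("all residual variances are zero or unusable; "
                          "returning unmoderated variances")
            return ModeratedVariances(d0=0.0, s02=float("nan"), s2_post=s2.copy())
        z = np.log(s2[ok])
        e = z - digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
        emean = float(e.mean())
        evar = float(e.var(ddof=1)) - float(np.mean(polygamma(1, df[ok] / 2.0))) if ok.sum() > 1 else 0.0
        if evar > 0:
            d0_est = 2.0 * _trigamma_inverse(evar)
            s02_est = float(np.exp(emean + digamma(d0_est / 2.0) - np.log(d0_est / 2.0)))
        else:
            d0_est = np.inf
            s02_est = float(np.exp(emean))
        d0 = d0_est if d0 is None else d0
        s02 = s02_est if s02 is None else s02

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        s2_post[~np.isfinite(s2)] = np.nan
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
    return ModeratedVariances(d0=float(d0), s02=float(s02), s2_post=s2_post)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def age_association(betas: pd.DataFrame, ages, d0: float | None = None) -> pd.DataFrame:
    """Full per-probe age-association table.

    Combines :func:`fit_age_linear_models`, :func:`moderate_variances` and
    :func:`bh_adjust`: columns ``slope``, ``intercept``, ``sigma2``, ``df``,
    ``s2_post``, ``t``, ``p_value``, ``q_value`` plus the scalar prior
    (``d0``, ``s02``) repeated per row for the audit trail.
    """
    fits = fit_age_linear_models(betas, ages)
    mod = moderate_variances(fits["sigma2"].to_numpy(), fits["df"].to_numpy(), d0=d0)
    s2_post = mod.s2_post
    with np.errstate(invalid="ignore", divide="ignore"):
        t = fits["slope"].to_numpy() / (np.sqrt(s2_post) * fits["se_unscaled"].to_numpy())
        df_total = fits["df"].to_numpy() + (0.0 if mod.d0 == 0 else mod.d0)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = fits.copy()
    out["s2_post"] = s2_post
    out["t"] = t
    out["p_value"] = p
    usable = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if usable.any():
        q[usable] = bh_adjust(p[usable])
    out["q_value"] = q
    out["d0"] = mod.d0
    out["s02"] = mod.s02
    return out


def select_age_probes(
    result: pd.DataFrame,
    betas: pd.DataFrame,
    q_threshold: float = 0.01,
    top_k: int = 1000,
) -> list[str]:
    """Significant age-associated probes ranked by across-sample β variance.

    Keeps probes with q < ``q_threshold``, ranks them by (n−1) variance over
    all samples descending (ties broken by probe id), and returns the top
    ``top_k`` (fewer if fewer pass).
    """
    sig = result.index[result["q_value"] < q_threshold]
    if len(sig) == 0:
        return []
    var = betas.loc[sig].var(axis=1, ddof=1)
    order = pd.DataFrame({"var": var, "probe": var.index}).sort_values(
        ["var", "probe"], ascending=[False, True]
    )
    return order["probe"].head(top_k).tolist()


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize (subtract mean, divide by the n−1 standard deviation).

    Constant rows map to all zeros with a warning.
    """
    vals = matrix.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, keepdims=True, ddof=1)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant rows standardized to zeros")
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (vals - mean) / sd_safe
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
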