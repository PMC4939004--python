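"""Cross-strain variability testing of accessible sites.

The count matrix is quantile normalized and each site is tested with a
negative-binomial (gamma-Poisson, variance = mu + alpha * mu^2)
likelihood-ratio test of strain-specific means against a common mean at a
fixed per-site dispersion. Dispersion is estimated by method of moments
pooled over within-strain replicates, floored at 1e-8, and shrunk 50/50
toward a mean-dispersion trend fitted across sites. The statistic is
referred to chi-squared with (n_strains - 1) df; Benjamini-Hochberg
adjusted p-values rank sites, and the top / bottom ``variable_fraction``
become the variable / common classes.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .stats import bh_adjust

ALPHA_FLOOR = 1e-8

__all__ = ["quantile_normalize", "nb_variability_test", "classify_sites",
           "bh_adjust", "round_half_away"]


def quantile_normalize(counts: np.ndarray) -> np.ndarray:
    """Force every column to the across-column mean distribution.

    Each column's values are replaced, in rank order, by the mean of the
    column-wise order statistics; ties within a column receive the mean of
    the target values their rank span covers.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty matrix")
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a sites x libraries matrix with >= 2 libraries")
    target = np.sort(counts, axis=0).mean(axis=1)
    out = np.empty_like(counts)
    n = counts.shape[0]
    for j in range(counts.shape[1]):
        col = counts[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = target
        # average the targets across tied runs
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [n]])
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[order[s:e]] = target[s:e].mean()
        out[:, j] = assigned
    return out


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 log-likelihood, continuous in y (gamma-function form), summed
    over the last axis. mu, alpha broadcast against y."""
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-10)
    ll = (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
          + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
    return ll.sum(axis=-1)


def estimate_dispersions(mat: np.ndarray, strain_index: np.ndarray):
    """Per-site dispersion: pooled within-strain method of moments, floored,
    then shrunk 50/50 toward an across-site trend alpha(mu) = a0 + a1/mu.

    Returns (alpha_hat, alpha_raw, trend_coeffs).
    """
    strains = np.unique(strain_index)
    n_sites = mat.shape[0]
    num = np.zeros(n_sites)
    den = np.zeros(n_sites)
    for s in strains:
        cols = np.flatnonzero(strain_index == s)
        if cols.size < 2:
            raise ValueError(f"strain {s!r} has < 2 replicates; dispersion unidentifiable")
        sub = mat[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += v - m
        den += m ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(den > 0, num / np.maximum(den, 1e-300), ALPHA_FLOOR)
    alpha_raw = np.maximum(alpha_raw, ALPHA_FLOOR)

    site_mean = mat.mean(axis=1)
    usable = site_mean > 0
    if usable.sum() >= 2:
        X = np.column_stack([np.ones(usable.sum()), 1.0 / site_mean[usable]])
        coef, *_ = np.linalg.lstsq(X, alpha_raw[usable], rcond=None)
    else:
        coef = np.array([alpha_raw.mean(), 0.0])
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.maximum(site_mean, 1e-300)
    trend = np.maximum(trend, ALPHA_FLOOR)
    alpha_hat = 0.5 * alpha_raw + 0.5 * trend
    return alpha_hat, alpha_raw, coef


def nb_variability_test(normalized: np.ndarray, strain_labels: Sequence[str],
                        sites: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Likelihood-ratio test per site of strain means vs a common mean.

    ``strain_labels`` gives the strain of each matrix column. Sites with
    all-zero values are reported untested (p = NaN, adjusted_p = 1,
    tested = False). Returns a DataFrame with per-strain fitted means,
    alpha, LRT, p, adjusted_p and rank.
    """
    mat = np.asarray(normalized, dtype=float)
    strain_index = np.asarray(strain_labels)
    strains = list(dict.fromkeys(strain_labels))
    if len(strains) < 2:
        raise ValueError("need >= 2 strains")
    alpha_hat, alpha_raw, _ = estimate_dispersions(mat, strain_index)

    n_sites = mat.shape[0]
    mu0 = mat.mean(axis=1)
    ll0 = _nb_loglik(mat, mu0[:, None], alpha_hat[:, None])
    ll1 = np.zeros(n_sites)
    strain_means = {}
    for s in strains:
        cols = np.flatnonzero(strain_index == s)
        mu_s = mat[:, cols].mean(axis=1)
        strain_means[s] = mu_s
        ll1 += _nb_loglik(mat[:, cols], mu_s[:, None], alpha_hat[:, None])
    lrt = np.maximum(2.0 * (ll1 - ll0), 0.0)
    df = len(strains) - 1
    tested = mat.sum(axis=1) > 0
    p = np.full(n_sites, np.nan)
    p[tested] = sps.chi2.sf(lrt[tested], df)
    adjusted = np.ones(n_sites)
    if tested.any():
        adjusted[tested] = bh_adjust(p[tested])

    out = pd.DataFrame({"alpha": alpha_hat, "alpha_raw": alpha_raw,
                        "lrt": lrt, "p": p, "adjusted_p": adjusted,
                        "tested": tested})
    for s in strains:
        out[f"mean_{s}"] = strain_means[s]
    if sites is not None:
        out = pd.concat([sites[["site_id", "chrom", "start", "end"]]
                         .reset_index(drop=True), out], axis=1)
    else:
        out.insert(0, "site_id", np.arange(n_sites))
        out.insert(1, "chrom", "")
        out.insert(2, "start", np.arange(n_sites))
        out.insert(3, "end", np.arange(n_sites) + 1)
    order = np.lexsort((out["start"].to_numpy(), out["chrom"].to_numpy(),
                        out["p"].fillna(np.inf).to_numpy(),
                        out["adjusted_p"].to_numpy()))
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(len(out))
    out["rank"] = ranks
    return out


def round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def classify_sites(results: pd.DataFrame, variable_fraction: float = 0.05) -> pd.DataFrame:
    """Label the top/bottom ``round(variable_fraction * n)`` sites (by
    adjusted p, ties broken by raw p then coordinates) variable/common."""
    if not (0 < variable_fraction < 0.5):
        raise ValueError("variable_fraction must be in (0, 0.5)")
    n = len(results)
    k = round_half_away(variable_fraction * n)
    out = results.copy()
    out["label"] = "neither"
    ranked = out.sort_values("rank")
    if k > 0:
        out.loc[ranked.index[:k], "label"] = "variable"
        out.loc[ranked.index[n - k:], "label"] = "common"
    return out
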