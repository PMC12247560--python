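"""Deviation scores, centile curves, and goodness-of-fit summaries.

A fitted normative model maps each observation back to the Gaussian
domain through the inverse of the standardising transform; the resulting
z-scores should be standard normal when the model is correctly specified.
Fit quality is summarised by the third and fourth standardised moments of
the z-scores (skew and excess kurtosis, both ideally 0), by qq data, and
by 1-vs-1 site classification AUC (ideally 0.5 for every site pair when
site effects have been absorbed by the model).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .shash import lambda_inverse, lambda_transform, sinh_arcsinh

__all__ = [
    "zscore",
    "zscore_mcmc",
    "centile_curves",
    "level_percentiles",
    "moments_report",
    "auc_matrix",
    "qq_data",
    "DEFAULT_LEVELS",
]

DEFAULT_LEVELS = np.arange(-3, 4)


def zscore(y, mu, sigma, epsilon=None, delta=None, family="shash_b"):
    """Deviation scores at one parameter point.

    For the moment-standardised family the score is the inverse of the
    generative transform, ``z = xi((y - mu)/sigma * eta + m1)``; with
    epsilon=0, delta=1 this reduces to the Gaussian ``(y - mu)/sigma``.
    """
    y = np.asarray(y, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    if family == "normal":
        return (y - mu) / sigma
    if family == "shash_o":
        return sinh_arcsinh((y - mu) / sigma, epsilon, delta)
    if family == "shash_b":
        return lambda_inverse(y, mu, sigma, epsilon, delta)
    raise ValueError(f"unknown family {family!r}")


def zscore_from_model(model, theta, y, X=None, batch=None):
    """Z-scores from a bound model at a parameter point (flat or dict)."""
    mu, sigma, eps, dlt = model.predict_likelihood_params(theta, X=X, batch=batch)
    return zscore(y, mu, sigma, eps, dlt, family=model.spec.family)


def zscore_mcmc(model, samples, y, X=None, batch=None, thin: int = 1):
    """Posterior z-scores: the per-draw score averaged over retained draws.

    With a single draw (or a degenerate posterior) this coincides with the
    point-estimate score at that draw.  ``thin`` keeps every k-th draw.
    """
    flat = samples.raw.reshape(-1, samples.raw.shape[-1])[::thin]
    if flat.shape[0] < 1:
        raise ValueError("need at least one post-burn-in draw")
    acc = np.zeros(np.asarray(y, dtype=float).shape)
    for row in flat:
        acc += zscore_from_model(model, row, y, X=X, batch=batch)
    return acc / flat.shape[0]


def level_percentiles(levels=DEFAULT_LEVELS) -> np.ndarray:
    """Percentile (0-100) reached by each Gaussian-space level."""
    return sps.norm.cdf(np.asarray(levels, dtype=float)) * 100.0


def centile_curves(mu, sigma, epsilon, delta, levels=DEFAULT_LEVELS,
                   grid: pd.DataFrame | None = None) -> pd.DataFrame:
    """Response values at fixed Gaussian-space levels across a grid.

    Each level g is pushed through the generative transform at the fitted
    per-grid-point parameters; g = {-3..3} correspond to the 0.1, 2.3,
    15.9, 50, 84.1, 97.7 and 99.9 percentiles.  Strictly increasing in g
    at every grid point (the transform is monotone).
    """
    levels = np.asarray(levels, dtype=float)
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    cols = {}
    for g in levels:
        cols[f"level_{g:+.0f}"] = lambda_transform(g, mu, sigma, epsilon, delta)
    out = pd.DataFrame(cols)
    if grid is not None:
        out = pd.concat([grid.reset_index(drop=True), out], axis=1)
    return out


def moments_report(z) -> pd.Series:
    """Skew and excess kurtosis of a z-score vector (ideal: both 0).

    Skew is the third standardised central moment; excess kurtosis the
    fourth minus 3, so a standard Gaussian scores 0 on both.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 8:
        raise ValueError("need at least 8 scores for stable moments")
    if np.var(z) == 0:
        raise ValueError("zero-variance scores have undefined moments")
    return pd.Series(
        {
            "skew": float(sps.skew(z, bias=True)),
            "excess_kurtosis": float(sps.kurtosis(z, fisher=True, bias=True)),
            "n": int(z.size),
        }
    )


def auc_matrix(z, batch, n_sites=None) -> np.ndarray:
    """|AUC - 0.5| for every ordered site pair, from z-scores as scores.

    Uses the rank (Mann-Whitney) statistic with midrank tie handling; a
    value of 0 means the two sites' score distributions are
    indistinguishable, 0.5 means perfectly separable.  Diagonal is 0 by
    convention; pairs involving an empty site are NaN.
    """
    z = np.asarray(z, dtype=float)
    batch = np.asarray(batch, dtype=int)
    S = int(n_sites if n_sites is not None else batch.max() + 1)
    if S < 2:
        raise ValueError("need at least two sites")
    out = np.zeros((S, S))
    groups = [z[batch == s] for s in range(S)]
    for i in range(S):
        for j in range(S):
            if i == j:
                continue
            zi, zj = groups[i], groups[j]
            if zi.size == 0 or zj.size == 0:
                out[i, j] = np.nan
                continue
            labels = np.r_[np.zeros(zi.size), np.ones(zj.size)]
            auc = roc_auc_score(labels, np.r_[zi, zj])
            out[i, j] = abs(auc - 0.5)
    return out


def qq_data(z):
    """Paired (theoretical, empirical) Gaussian quantiles for qq plotting."""
    z = np.sort(np.asarray(z, dtype=float))
    n = z.size
    theo = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theo, z


def evaluation_table(rows: dict) -> pd.DataFrame:
    """Assemble a moments report table (one row per phenotype/model pair)."""
    recs = []
    for name, z in rows.items():
        rec = moments_report(z)
        rec.name = name
        recs.append(rec)
    return pd.DataFrame(recs)
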