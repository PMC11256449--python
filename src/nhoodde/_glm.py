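"""Vectorized negative-binomial GLM machinery for pseudo-bulk testing.

All fitting routines operate on a gene x sample count matrix simultaneously
for every gene: the design matrix is shared across genes, so one IRLS sweep
solves G small weighted least-squares systems with a single batched
``np.linalg.solve``.  On top of the GLM fits sit

* Cox-Reid adjusted profile likelihood (APL) dispersion estimation on a
  log-spaced grid with quadratic interpolation,
* a lowess trend of gene-wise dispersions on average log-CPM with
  empirical-Bayes shrinkage toward the trend (moment-matched prior df), and
* F-distribution moment matching ("squeezing") of quasi-dispersions, the
  second-level dispersion that models the variability of per-gene variance
  estimates and drives the quasi-likelihood F-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

_MIN_MU = 1e-8
_MIN_DISP = 1e-10
_ETA_CLIP = 50.0


def nb_deviance(y: np.ndarray, mu: np.ndarray, disp) -> np.ndarray:
    """Per-gene NB residual deviance, summed over samples.

    Unit deviance 2*[y*log(y/mu) - (y + 1/phi)*log((1+phi*y)/(1+phi*mu))];
    the Poisson limit is recovered smoothly as phi -> 0.
    """
    mu = np.maximum(mu, _MIN_MU)
    disp = np.maximum(np.asarray(disp, dtype=float), _MIN_DISP)
    t1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    t2 = (y + 1.0 / disp) * (np.log1p(disp * y) - np.log1p(disp * mu))
    return 2.0 * (t1 - t2).sum(axis=-1)


def nb_loglik(y: np.ndarray, mu: np.ndarray, disp) -> np.ndarray:
    """Per-gene NB log-likelihood, summed over samples."""
    mu = np.maximum(mu, _MIN_MU)
    disp = np.maximum(np.asarray(disp, dtype=float), _MIN_DISP)
    r = 1.0 / disp
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + np.where(y > 0, y * (np.log(disp * mu) - np.log1p(disp * mu)), 0.0)
        - r * np.log1p(disp * mu)
    )
    return ll.sum(axis=-1)


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    disp,
    max_iter: int = 50,
    tol: float = 1e-8,
    ridge: float = 1e-8,
):
    """Fit log-link NB GLMs for all genes at once by IRLS.

    Parameters
    ----------
    y
        Gene x sample counts.
    X
        Sample x coefficient design matrix, shared across genes.
    offset
        Per-sample log offsets (log of effective library size).
    disp
        NB dispersion, scalar or per-gene vector.

    Returns
    -------
    beta : (G, p) natural-log-scale coefficients
    mu : (G, n) fitted means
    dev : (G,) residual deviances
    weights : (G, n) final IRLS working weights mu/(1 + disp*mu)
    """
    y = np.asarray(y, dtype=float)
    G, n = y.shape
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    disp = np.broadcast_to(np.asarray(disp, dtype=float), (G,)).reshape(G, 1)
    disp = np.maximum(disp, _MIN_DISP)
    offset = np.asarray(offset, dtype=float).reshape(1, n)

    mu = y + np.mean(y, axis=1, keepdims=True) * 0.1 + 0.1
    eta0 = np.log(mu) - offset
    beta = eta0 @ np.linalg.pinv(X).T
    dev = np.full(G, np.inf)
    eye = ridge * np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + disp * mu)
        z = (eta - offset) + (y - mu) / np.maximum(mu, _MIN_MU)
        xtwx = np.einsum("gn,ni,nj->gij", w, X, X) + eye
        xtwz = np.einsum("gn,gn,ni->gi", w, z, X)
        beta_new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        eta_new = np.clip(beta_new @ X.T + offset, -_ETA_CLIP, _ETA_CLIP)
        dev_new = nb_deviance(y, np.exp(eta_new), disp)
        delta = np.max(np.abs(dev_new - dev) / (np.abs(dev_new) + 1.0))
        beta = beta_new
        dev = dev_new
        if delta < tol:
            break
    eta = np.clip(beta @ X.T + offset, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    w = mu / (1.0 + disp * mu)
    return beta, mu, dev, w


def adjusted_profile_loglik(y, X, offset, disp) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood of ``disp`` for every gene.

    The CR adjustment subtracts 0.5*logdet(X' W X), removing the bias from
    estimating the mean parameters alongside the dispersion.
    """
    _, mu, _, w = fit_nb_glm(y, X, offset, disp)
    ll = nb_loglik(y, mu, np.broadcast_to(np.asarray(disp, float), (y.shape[0],)).reshape(-1, 1))
    p = X.shape[1]
    xtwx = np.einsum("gn,ni,nj->gij", w, X, X) + 1e-10 * np.eye(p)
    _, logdet = np.linalg.slogdet(xtwx)
    return ll - 0.5 * logdet


def _grid_argmax_interpolate(log_grid: np.ndarray, apl: np.ndarray) -> np.ndarray:
    """Quadratic interpolation of the per-gene APL maximum on a log-disp grid."""
    j = np.argmax(apl, axis=0)
    G = apl.shape[1]
    log_d = log_grid[j].astype(float)
    interior = (j > 0) & (j < len(log_grid) - 1)
    idx = np.where(interior)[0]
    if idx.size:
        lm = apl[j[idx] - 1, idx]
        l0 = apl[j[idx], idx]
        lp = apl[j[idx] + 1, idx]
        denom = lm - 2.0 * l0 + lp
        delta = np.where(denom < 0, 0.5 * (lm - lp) / denom, 0.0)
        delta = np.clip(delta, -1.0, 1.0)
        step = log_grid[1] - log_grid[0]
        log_d[idx] = log_grid[j[idx]] + delta * step
    return log_d


@dataclass
class DispersionFit:
    """Gene-wise, trended and tagwise NB dispersions plus shrinkage metadata."""

    genewise: np.ndarray
    trended: np.ndarray
    tagwise: np.ndarray
    ave_log_cpm: np.ndarray
    prior_df: float
    residual_df: int


def estimate_nb_dispersions(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    grid_range: tuple[float, float] = (1e-4, 10.0),
    grid_length: int = 13,
    trend_span: float = 0.4,
    min_prior_df: float = 3.0,
) -> DispersionFit:
    """Estimate NB dispersions as a function of gene abundance.

    Gene-wise dispersions maximize the CR-adjusted profile likelihood on a
    log-spaced grid (with quadratic interpolation); the trend is a lowess fit
    of log dispersion on average log-CPM; tagwise values shrink the gene-wise
    estimates toward the trend with a moment-matched prior df (floored at
    ``min_prior_df``) so that sparse designs borrow strength across genes.
    """
    y = np.asarray(y, dtype=float)
    G, n = y.shape
    res_df = n - X.shape[1]
    if res_df < 1:
        raise InvalidDesignError("residual degrees of freedom < 1")
    lib = np.exp(np.asarray(offset, dtype=float))
    ave_log_cpm = np.log2((y / lib * 1e6).mean(axis=1) + 0.5)

    grid = np.logspace(np.log10(grid_range[0]), np.log10(grid_range[1]), grid_length)
    log_grid = np.log(grid)
    apl = np.stack([adjusted_profile_loglik(y, X, offset, d) for d in grid])
    log_genewise = _grid_argmax_interpolate(log_grid, apl)
    genewise = np.exp(log_genewise)

    if G >= 20:
        fitted = lowess(
            log_genewise, ave_log_cpm, frac=trend_span, it=1, return_sorted=False
        )
        # lowess can return NaN at duplicated extremes; fall back to the mean
        fitted = np.where(np.isfinite(fitted), fitted, np.mean(log_genewise))
        trended = np.exp(fitted)
    else:
        trended = np.full(G, np.exp(np.mean(log_genewise)))
    if G == 1:
        trended = genewise.copy()

    resid = log_genewise - np.log(trended)
    samp_var = 2.0 / res_df  # delta-method scale of a log-dispersion estimate
    if G > 1:
        prior_var = max(float(np.var(resid, ddof=1)) - samp_var, 1e-8)
    else:
        prior_var = 1e-8
    prior_df = max(2.0 / prior_var, min_prior_df)
    shrink = res_df / (res_df + prior_df)
    tagwise = trended * (genewise / trended) ** shrink
    return DispersionFit(
        genewise=genewise,
        trended=trended,
        tagwise=tagwise,
        ave_log_cpm=ave_log_cpm,
        prior_df=float(prior_df),
        residual_df=int(res_df),
    )


class InvalidDesignError(ValueError):
    """Design matrix leaves no residual degrees of freedom or is rank deficient."""


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, well-conditioned)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def squeeze_var(s2: np.ndarray, df: float):
    """Empirical-Bayes moment matching of scaled-F distributed variances.

    Treats s2 ~ s2_0 * F(df, d0) and estimates (d0, s2_0) from the first two
    moments of log s2.  Returns (d0, s2_0, s2_post) where the posterior
    variance is the df-weighted combination of prior and observed values;
    d0 = inf collapses every variance onto the common prior value.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-10)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if len(s2) < 2:
        d0, s2_0 = np.inf, float(np.exp(emean))
    else:
        evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
        if evar > 0:
            d0 = 2.0 * trigamma_inverse(evar)
            s2_0 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            d0, s2_0 = np.inf, float(np.exp(emean))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s2_0)
    else:
        s2_post = (d0 * s2_0 + df * s2) / (d0 + df)
    return d0, s2_0, s2_post
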