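"""Hypothesis tests on posterior draws and convergence diagnostics.

Global test: H0 that the tissue-wide mean slope, mean_k beta1(s_k), is 0,
assessed through the equal-tailed credible interval of the per-draw spatial
mean and through the probability of direction p_d (the posterior share
matching the sign of the median), with P_two = 2 (1 - p_d) acting as a
two-sided p-value.  Local tests call a location significant when its
credible interval excludes 0.  BH controls the FDR across pairs; the
Geweke z-score (means of the first 10% vs last 50% of a chain, scaled by
spectral-density-at-zero variance estimates) flags non-converged chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.regression.linear_model import yule_walker
from statsmodels.stats.multitest import multipletests

from .sampler import PosteriorDraws

__all__ = [
    "CoexpressionResult",
    "probability_of_direction",
    "global_test",
    "local_test",
    "bh_adjust",
    "geweke_z",
    "summarize",
]


@dataclass
class CoexpressionResult:
    mean_slope: float = np.nan
    global_ci: tuple = (np.nan, np.nan)
    global_pd: float = np.nan
    global_p: float = np.nan
    global_sig: bool = False
    mean_slope_draws: np.ndarray | None = None
    local_ci: np.ndarray | None = None
    local_sig: np.ndarray | None = None
    beta1_mean: np.ndarray | None = None
    geweke_z: np.ndarray | None = None
    level: float = 0.95
    meta: dict = field(default_factory=dict)


def probability_of_direction(draws) -> float:
    """p_d in [0.5, 1]: posterior share with the sign of the median.

    Draws exactly at zero count toward both sign fractions, so degenerate
    all-zero chains give p_d = 1 (and P_two = 0 is avoided by the caller
    checking the CI, which then includes 0).
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 2:
        raise ValueError("need at least 2 draws")
    f_pos = np.mean(draws >= 0.0)
    f_neg = np.mean(draws <= 0.0)
    return float(max(f_pos, f_neg))


def _p_two(draws) -> float:
    return 2.0 * (1.0 - probability_of_direction(draws))


def global_test(draws: PosteriorDraws | np.ndarray, level: float = 0.95,
                alpha: float = 0.05) -> CoexpressionResult:
    """Test the tissue-wide mean slope; significant iff P_two < alpha."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    ms = draws.mean_slope if isinstance(draws, PosteriorDraws) \
        else np.asarray(draws, dtype=float).ravel()
    if ms.size == 0:
        raise ValueError("no draws")
    lo, hi = np.quantile(ms, [(1 - level) / 2, 1 - (1 - level) / 2])
    p = _p_two(ms)
    pd = probability_of_direction(ms)
    return CoexpressionResult(
        mean_slope=float(ms.mean()), global_ci=(float(lo), float(hi)),
        global_pd=pd, global_p=p, global_sig=bool(p < alpha),
        mean_slope_draws=ms, level=level,
    )


def local_test(draws: PosteriorDraws | np.ndarray, level: float = 0.95):
    """Per-location equal-tailed CIs; significant iff the CI excludes 0.

    Returns (sig_mask, ci) with ci of shape (n, 2).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    b1 = draws.beta1 if isinstance(draws, PosteriorDraws) \
        else np.asarray(draws, dtype=float)
    if b1.ndim != 2 or b1.shape[0] == 0:
        raise ValueError("need a (draws, locations) matrix")
    ci = np.quantile(b1, [(1 - level) / 2, 1 - (1 - level) / 2], axis=0).T
    sig = (ci[:, 0] > 0) | (ci[:, 1] < 0)
    return sig, ci


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _spectrum0(x: np.ndarray) -> float:
    """Spectral density at frequency zero via an AR fit (AIC order choice)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    v = x.var()
    if v == 0:
        return 0.0
    max_order = min(20, n // 10)
    best = (np.inf, v)
    for order in range(0, max_order + 1):
        if order == 0:
            s2, v_innov = v, v
        else:
            rho, sv = yule_walker(x, order=order, method="mle")
            v_innov = sv**2
            s2 = v_innov / (1.0 - rho.sum()) ** 2
        aic = n * np.log(max(v_innov, 1e-300)) + 2.0 * order
        if aic < best[0] and np.isfinite(s2) and s2 > 0:
            best = (aic, s2)
    return float(best[1])


def geweke_z(chain, frac_first: float = 0.1, frac_last: float = 0.5) -> float:
    """Geweke convergence z-score; |z| > 2 is conventionally flagged."""
    chain = np.asarray(chain, dtype=float).ravel()
    n = chain.size
    if n < 100:
        raise ValueError("chain too short for the Geweke diagnostic (need >= 100)")
    a = chain[: int(frac_first * n)]
    b = chain[n - int(frac_last * n):]
    if a.var() == 0 and b.var() == 0:
        warnings.warn("constant chain: Geweke z set to 0", stacklevel=2)
        return 0.0
    va = _spectrum0(a) / a.size
    vb = _spectrum0(b) / b.size
    denom = np.sqrt(va + vb)
    if denom == 0:
        warnings.warn("zero variance estimate: Geweke z set to 0", stacklevel=2)
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def summarize(draws: PosteriorDraws, level: float = 0.95,
              alpha: float = 0.05, geweke: bool = True) -> CoexpressionResult:
    """Full per-pair summary: global + local tests, Geweke per location."""
    res = global_test(draws, level=level, alpha=alpha)
    sig, ci = local_test(draws, level=level)
    res.local_sig, res.local_ci = sig, ci
    res.beta1_mean = draws.beta1.mean(axis=0)
    if geweke and draws.beta1.shape[0] >= 100:
        res.geweke_z = np.array([geweke_z(draws.beta1[:, k])
                                 for k in range(draws.beta1.shape[1])])
    res.meta = dict(draws.meta)
    return res
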