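"""Random field theory for smooth 1-D statistic fields.

Family-wise inference over the 101-node gait-cycle grid treats the
statistic curve as a smooth stationary random field. The critical
threshold u* at level alpha solves

    alpha = P0(u) + resels * EC1(u)

where P0 is the pointwise survival function, resels = (Q - 1) / FWHM is
the number of resolution elements of the search interval, and EC1 is
the 1-D Euler-characteristic density of the field type (Worsley 1994;
Friston et al. 1994):

    Gaussian:  sqrt(4 ln 2) / (2 pi) * exp(-u^2 / 2)
    t (v):     sqrt(4 ln 2) / (2 pi) * (1 + u^2/v)^(-(v-1)/2)
    chi2 (k):  sqrt(4 ln 2) / (2 pi) * u^((k-1)/2) e^(-u/2)
               / (2^((k-2)/2) Gamma(k/2))
    F (k, v):  sqrt(4 ln 2) / (2 pi) * sqrt(2)
               * Gamma((v+k-1)/2) / (Gamma(v/2) Gamma(k/2))
               * (k u / v)^((k-1)/2) * (1 + k u / v)^(-(v+k-2)/2)

Suprathreshold cluster p-values use the standard expected-cluster
approximation for one dimension: with expected cluster count
E[N] = P0 + resels * EC1 and expected suprathreshold volume
E[S] = resels * P0, the extent (in resels) of a single cluster is taken
exponential-type with P(extent >= s) = exp(-beta s^2),
beta = (Gamma(3/2) E[N] / E[S])^2, and
p_cluster = 1 - exp(-E[N] * P(extent >= s)).

Field smoothness (FWHM, in nodes) is estimated from the normalized
residual gradients pooled over observations and vector components.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.special import gammaln

from .exceptions import SignalError

__all__ = [
    "ec_density",
    "survival",
    "fwe_pvalue",
    "critical_threshold",
    "cluster_pvalue",
    "estimate_fwhm",
    "resel_count",
]

_SQRT_4LN2 = np.sqrt(4.0 * np.log(2.0))


def ec_density(u, stat: str, df) -> float:
    """1-D Euler-characteristic density at height ``u``.

    Gaussian/t fields carry the Rice-rate prefactor sqrt(4 ln 2)/(2 pi);
    chi2/F fields carry sqrt(4 ln 2 / (2 pi)) because their derivative
    variance grows with the field height (Worsley 1994).
    """
    u = np.asarray(u, dtype=float)
    c = _SQRT_4LN2 / (2.0 * np.pi)
    c2 = np.sqrt(4.0 * np.log(2.0) / (2.0 * np.pi))
    if stat == "gauss":
        return c * np.exp(-0.5 * u**2)
    if stat == "t":
        (v,) = _as_tuple(df, 1)
        return c * (1.0 + u**2 / v) ** (-0.5 * (v - 1.0))
    if stat == "chi2":
        (k,) = _as_tuple(df, 1)
        with np.errstate(invalid="ignore"):
            out = (
                c2
                * u ** (0.5 * (k - 1.0))
                * np.exp(-0.5 * u - gammaln(0.5 * k))
                / 2.0 ** (0.5 * (k - 2.0))
            )
        return np.where(u > 0, out, c2)
    if stat == "F":
        k, v = _as_tuple(df, 2)
        lg = gammaln(0.5 * (v + k - 1.0)) - gammaln(0.5 * v) - gammaln(0.5 * k)
        with np.errstate(invalid="ignore"):
            out = (
                c2
                * np.sqrt(2.0)
                * np.exp(lg)
                * (k * u / v) ** (0.5 * (k - 1.0))
                * (1.0 + k * u / v) ** (-0.5 * (v + k - 2.0))
            )
        return np.where(u > 0, out, c2)
    raise ValueError(f"unknown field type {stat!r}")


def _as_tuple(df, n):
    t = tuple(np.atleast_1d(df).astype(float))
    if len(t) != n:
        raise ValueError(f"field type needs {n} dof parameter(s), got {t}")
    return t


def survival(u, stat: str, df) -> float:
    """Pointwise (single-node) survival function."""
    if stat == "gauss":
        return stats.norm.sf(u)
    if stat == "t":
        return stats.t.sf(u, *_as_tuple(df, 1))
    if stat == "chi2":
        return stats.chi2.sf(u, *_as_tuple(df, 1))
    if stat == "F":
        return stats.f.sf(u, *_as_tuple(df, 2))
    raise ValueError(f"unknown field type {stat!r}")


def fwe_pvalue(u, stat: str, df, resels: float) -> float:
    """P(max of the field exceeds u), expected-EC upper bound, capped at 1."""
    p = survival(u, stat, df) + resels * ec_density(u, stat, df)
    return float(min(1.0, p))


def critical_threshold(alpha: float, stat: str, df, resels: float) -> float:
    """Height u* with family-wise exceedance probability ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")

    def f(u):
        return fwe_pvalue(u, stat, df, resels) - alpha

    lo, hi = 1e-6, 10.0
    while f(hi) > 0 and hi < 1e6:
        hi *= 2.0
    if f(lo) < 0:  # already below alpha everywhere (tiny resels, silly alpha)
        return lo
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def cluster_pvalue(u: float, extent_resels: float, stat: str, df,
                   resels: float) -> float:
    """RFT p-value of one suprathreshold cluster of the given extent."""
    p0 = survival(u, stat, df)
    en = p0 + resels * ec_density(u, stat, df)  # expected cluster count
    es = resels * p0  # expected suprathreshold resels
    if en <= 0 or es <= 0:
        return 1.0
    from scipy.special import gamma as _gamma

    beta = (_gamma(1.5) * en / es) ** 2
    p_ext = np.exp(-beta * max(extent_resels, 0.0) ** 2)
    return float(min(1.0, 1.0 - np.exp(-en * p_ext)))


def resel_count(n_nodes: int, fwhm: float) -> float:
    """Resolution elements of a line search region of ``n_nodes`` nodes."""
    return (n_nodes - 1) / fwhm


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Field smoothness (FWHM, nodes) from residual gradients.

    ``residuals`` is (n_observations, Q); vector components may be
    stacked along the first axis (pooled estimate). Uses the normalized
    gradient-variance estimator: FWHM = sqrt(4 ln 2 / mean(d^2)) with d
    the node-to-node differences of the variance-normalized residuals.

    Raises
    ------
    SignalError
        If the residuals are (numerically) constant so smoothness is
        undefined.
    """
    R = np.atleast_2d(np.asarray(residuals, dtype=float))
    ssq = (R**2).sum(axis=0)
    dy = np.diff(R, axis=1)
    v = (dy**2).sum(axis=0)
    denom = 0.5 * (ssq[:-1] + ssq[1:])
    ok = denom > 1e-30
    if not ok.any():
        raise SignalError("constant residuals: field smoothness undefined")
    resels_per_node = np.sqrt(v[ok] / denom[ok] / (4.0 * np.log(2.0)))
    mean_rpn = resels_per_node.mean()
    if mean_rpn < 1e-12:
        raise SignalError("residuals have no temporal variation: FWHM undefined")
    return float(1.0 / mean_rpn)
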