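"""Exact numerical power for two active doses, two stages, no early stopping.

In the idealized setting -- two treatments versus control, equal allocation,
unit variance, no interim stopping or selection -- the global power of the
cumulative max-score test and of the inverse-normal combination test can be
written as four-fold integrals over the stage-1 scores and the stage-2
incremental scores.  The two expressions differ only in the acceptance
region of the inner integral: the cumulative test accepts on
(-inf, b_2 - w_11) x (-inf, b_2 - w_21) (a sufficient-statistic test), the
combination test on (-inf, u)^2 with the data-dependent limit
u = F_(2)^{-1}( Phi((z_alpha - h_1 z_{p_1}) / h_2) ), where F_(2) is the
null CDF of the maximum incremental score and p_1 the stage-1 adjusted
p-value.  Both integrals are evaluated by tensor Gauss-Hermite quadrature
over the stage-1 law with exact inner bivariate rectangle probabilities
(absolute accuracy well below 5e-4).

The module also provides single-stage Dunnett power and sample size for
many-to-one comparisons, used to size the reference design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from ._quad import _gh, bvn_lower, onefactor_lower, onefactor_t_lower

__all__ = ["AnalyticSetting", "p_cumul", "p_stage",
           "dunnett_critical_value", "dunnett_single_stage_power",
           "dunnett_sample_size"]

_N_OUTER = 64


@dataclass(frozen=True)
class AnalyticSetting:
    """Design constants of the idealized two-dose comparison.

    ``info1``/``info2`` are the cumulative informations per comparison at
    the two analyses; weights must satisfy h1^2 + h2^2 = 1.  The final
    critical value b2 (score scale) defaults to the two-comparison
    single-look Dunnett value at level alpha on the final information.
    """

    delta: tuple = (0.0, 0.0)
    info1: float = 0.5
    info2: float = 1.0
    alpha: float = 0.05
    weights: tuple = None
    b2: float = None

    def __post_init__(self):
        if not 0 < self.info1 < self.info2:
            raise ValueError("need 0 < info1 < info2")
        w = self.weights
        if w is None:
            w = (np.sqrt(self.info1 / self.info2),
                 np.sqrt(1.0 - self.info1 / self.info2))
        if abs(w[0] ** 2 + w[1] ** 2 - 1.0) > 1e-12:
            raise ValueError("weights must satisfy h1^2 + h2^2 = 1")
        object.__setattr__(self, "weights", tuple(map(float, w)))
        if self.b2 is None:
            c = dunnett_critical_value(2, self.alpha, df=np.inf)
            object.__setattr__(self, "b2", c * np.sqrt(self.info2))

    @property
    def inc_info(self) -> float:
        return self.info2 - self.info1


def _outer_nodes(setting: AnalyticSetting, n: int):
    """Tensor nodes (w11, w21) of the stage-1 score law and their weights.

    The stage-1 scores are N(delta * I1, I1 * [[1, .5], [.5, 1]]); the
    one-factor representation (shared control) gives independent integration
    variables."""
    z, w = _gh(n)
    a = np.sqrt(0.5)
    sd = np.sqrt(setting.info1)
    mu = np.asarray(setting.delta) * setting.info1
    zf = z[:, None, None]
    z1 = z[None, :, None]
    z2 = z[None, None, :]
    w11 = mu[0] + sd * (a * zf + a * z1)
    w21 = mu[1] + sd * (a * zf + a * z2)
    wt = (w[:, None, None] * w[None, :, None] * w[None, None, :])
    return w11, w21, wt


def _inner_rect(setting: AnalyticSetting, u1, u2):
    """P(W1(2) < u1, W2(2) < u2) under the true deltas; exact bivariate."""
    sd = np.sqrt(setting.inc_info)
    mu = np.asarray(setting.delta) * setting.inc_info
    return bvn_lower((u1 - mu[0]) / sd, (u2 - mu[1]) / sd, 0.5)


def p_cumul(setting: AnalyticSetting, n_nodes: int = _N_OUTER) -> float:
    """Global power of the cumulative max-score test (no early stopping):
    reject when max_i (w_i1 + w_i(2)) >= b2."""
    w11, w21, wt = _outer_nodes(setting, n_nodes)
    accept = _inner_rect(setting, setting.b2 - w11, setting.b2 - w21)
    return float(np.clip(1.0 - np.sum(wt * accept), 0.0, 1.0))


def p_stage(setting: AnalyticSetting, n_nodes: int = 800) -> float:
    """Global power of the inverse-normal combination test: reject when
    h1 z_{p1} + h2 z_{p(2)} >= z_alpha with max-score adjusted p-values.

    The acceptance region depends on the stage-1 data only through
    m = max(w_11, w_21), so the four-fold integral collapses to a single
    smooth integral over the exact density of the stage-1 maximum.
    """
    h1, h2 = setting.weights
    z_alpha = norm.ppf(1.0 - setting.alpha)
    sd1 = np.sqrt(setting.info1)
    mu = np.asarray(setting.delta) * setting.info1
    lo = mu.min() - 9.5 * sd1
    hi = mu.max() + 9.5 * sd1
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    m = (x + 1.0) / 2.0 * (hi - lo) + lo
    wts = w * (hi - lo) / 2.0
    # exact density of the maximum of a bivariate normal, correlation 1/2
    rho, s = 0.5, sd1
    z0 = (m[:, None] - mu[None, :]) / s
    cond = (z0[:, ::-1] - rho * z0) / np.sqrt(1.0 - rho ** 2)
    dens = np.sum(_phi(z0) / s * ndtr(cond), axis=1)
    # 1 - p1 = null CDF of the stage-1 max evaluated at m
    F0 = onefactor_lower(np.repeat(m[:, None], 2, axis=1),
                         np.full(2, np.sqrt(0.5)), sd=sd1)
    zp1 = ndtri(np.clip(F0, 1e-16, 1.0 - 1e-16))
    g = ndtr((z_alpha - h1 * zp1) / h2)
    sd2 = np.sqrt(setting.inc_info)
    grid2, F2 = _max_cdf_grid(sd2)
    u = np.interp(g, F2, grid2)     # F_(2)^{-1}(g), monotone interpolation
    accept = _inner_rect(setting, u, u)
    return float(np.clip(1.0 - wts @ (dens * accept), 0.0, 1.0))


def _phi(x):
    return np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


@lru_cache(maxsize=32)
def _max_cdf_grid(sd: float, lo: float = -9.0, hi: float = 9.0,
                  n: int = 6001):
    """Dense grid of the null CDF of max(W_1(2), W_2(2)) (correlation 1/2,
    standard deviation ``sd``) for monotone interpolation and inversion."""
    x = np.linspace(lo * sd, hi * sd, n)
    F = onefactor_lower(np.repeat(x[:, None], 2, axis=1),
                        np.full(2, np.sqrt(0.5)), sd=sd)
    return x, np.clip(F, 0.0, 1.0)


# -- single-stage Dunnett design ------------------------------------------

def dunnett_critical_value(k: int, alpha: float, df: float,
                           loadings=None) -> float:
    """One-sided critical value c with P0(max_i T_i >= c) = alpha for the
    k-variate (t or, for df=inf, normal) many-to-one comparison law."""
    if loadings is None:
        loadings = np.full(k, np.sqrt(0.5))

    def f(c):
        return 1.0 - float(onefactor_t_lower(np.full(k, c), loadings, df)) \
            - alpha

    return brentq(f, 0.0, 12.0, xtol=1e-10)


def dunnett_single_stage_power(delta, sigma: float, n_per_arm: int,
                               alpha: float = 0.025, k: int = None,
                               known_variance: bool = True) -> float:
    """Global power (reject at least one arm) of a single-stage Dunnett test.

    Equal allocation: n patients on each of the k treatments and on control;
    the per-arm noncentrality is delta_i * sqrt(n / (2 sigma^2)).  The
    default is the design-stage (known-variance, normal-theory) convention;
    ``known_variance=False`` uses the exact multivariate t with
    (k+1)(n-1) pooled degrees of freedom.
    """
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    k = delta.size if k is None else k
    delta = np.broadcast_to(delta, (k,))
    ncp = delta * np.sqrt(n_per_arm / (2.0 * sigma ** 2))
    a = np.full(k, np.sqrt(0.5))
    if known_variance:
        c = _cached_crit(k, alpha, np.inf)
        return float(np.clip(1.0 - onefactor_lower(c - ncp, a), 0.0, 1.0))
    df = (k + 1) * (n_per_arm - 1)
    c = _cached_crit(k, alpha, df)
    # noncentral: T_i = (Z_i + ncp_i) / S; integrate the chi mixture
    from scipy.stats import chi
    from ._quad import _gl01
    q, w = _gl01(64)
    s = chi.ppf(q, df) / np.sqrt(df)
    upper = c * s[:, None] - ncp[None, :]
    vals = onefactor_lower(upper, a)
    return float(np.clip(1.0 - vals @ w, 0.0, 1.0))


@lru_cache(maxsize=128)
def _cached_crit(k, alpha, df):
    return dunnett_critical_value(k, alpha, df)


def dunnett_sample_size(delta, sigma: float, target_power: float,
                        alpha: float = 0.025, k: int = None,
                        known_variance: bool = True,
                        n_max: int = 100000) -> int:
    """Smallest equal per-arm sample size reaching the target global power."""
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    k = delta.size if k is None else k
    if np.all(delta <= 0):
        raise ValueError("power target unreachable with nonpositive effects")

    def power(n):
        return dunnett_single_stage_power(delta, sigma, n, alpha, k,
                                          known_variance)

    lo, hi = 2, 4
    while power(hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError("target power unreachable below n_max")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi
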