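"""Error spending and group-sequential efficacy boundaries for max statistics.

Boundaries (b_1, ..., b_J) for monitoring max_i W_ij solve the stage-wise
exit-probability equations under the global null,

    P0(max W_1 >= b_1) = alpha_1,
    P0(max W_1 < b_1, ..., max W_j >= b_j) = alpha_j,

with alpha_j the increment of the spending function at the stage-j
information fraction.  k = 1 recovers the classical two-arm boundaries.
Solutions are reported on the Wald scale (b_j / sqrt(I_j), standard normal
under the null) and cached per configuration.  The small-sample t-scale
transformation maps a score boundary through the Student quantile so that
plug-in estimated information does not inflate the type-1 error.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm, t as t_dist

from ._quad import onefactor_lower, path_exit_probs, path_lower

__all__ = [
    "ld_obf_spending",
    "GSBoundaries",
    "max_stat_boundaries",
    "max_stat_exit_prob",
    "t_adjust_boundary",
]

_BRACKET = (0.0, 12.0)   # Wald scale
_XTOL = 1e-9


def ld_obf_spending(t: float, alpha: float) -> float:
    """Lan-DeMets O'Brien-Fleming-type cumulative error spent by information
    fraction ``t``: f(t) = 2 - 2 * Phi(Phi^{-1}(1 - alpha/2) / sqrt(t))."""
    t = float(t)
    if t <= 0.0:
        raise ValueError("information fraction must be positive")
    if t > 1.0 + 1e-12:
        raise ValueError("information fraction must not exceed 1")
    return float(2.0 - 2.0 * norm.cdf(norm.ppf(1.0 - alpha / 2.0)
                                      / np.sqrt(min(t, 1.0))))


_SPENDING = {"ldobf": ld_obf_spending}


@dataclass(frozen=True)
class GSBoundaries:
    """Group-sequential efficacy boundaries for ``n_comparisons`` arms.

    ``wald`` holds b_j / sqrt(I_j); ``alpha_spent`` the per-stage exit
    probability under the global null (sums to alpha)."""

    wald: tuple
    alpha_spent: tuple
    n_comparisons: int
    info_fractions: tuple
    alpha: float

    def score_values(self, info) -> np.ndarray:
        """Boundaries on the score scale for cumulative informations ``info``
        (one value per stage, or per stage and arm)."""
        info = np.asarray(info, dtype=float)
        w = np.asarray(self.wald)
        return (w.reshape(w.shape + (1,) * (info.ndim - 1)) * np.sqrt(info)
                if info.ndim > 1 else w * np.sqrt(info))

    def t_adjusted(self, stage: int, est_info, df) -> np.ndarray:
        """Score-scale boundary at ``stage`` (1-based) after the small-sample
        t transformation with estimated information and df."""
        b = self.wald[stage - 1] * np.sqrt(np.asarray(est_info, dtype=float))
        return t_adjust_boundary(b, est_info, df)


@lru_cache(maxsize=256)
def _boundaries_cached(k, fractions, alpha, spending, loadings):
    spend = _SPENDING[spending]
    fr = np.asarray(fractions)
    cum = np.array([spend(t, alpha) for t in fr])
    alpha_j = np.diff(np.r_[0.0, cum])
    a = np.asarray(loadings)
    inc_sd = np.sqrt(np.diff(np.r_[0.0, fr]))[:, None] * np.ones((1, k))
    wald = []
    noncross_prev = 1.0
    for j, aj in enumerate(alpha_j):
        tj = np.sqrt(fr[j])

        def exceed(e):
            upper = np.array([[w * np.sqrt(fr[i])] * k
                              for i, w in enumerate(wald)] + [[e * tj] * k])
            return noncross_prev - path_lower(upper, inc_sd[:j + 1], a) - aj

        lo, hi = _BRACKET
        if exceed(hi) > 0:  # alpha_j too small to reach within bracket
            bj = hi
        else:
            bj = brentq(exceed, lo, hi, xtol=_XTOL)
        wald.append(bj)
        noncross_prev -= aj
    return GSBoundaries(wald=tuple(wald), alpha_spent=tuple(alpha_j),
                        n_comparisons=k, info_fractions=tuple(fr),
                        alpha=alpha)


def max_stat_boundaries(k: int, info_fractions, alpha: float,
                        spending: str = "ldobf",
                        loadings=None) -> GSBoundaries:
    """Efficacy boundaries for the maximum of ``k`` correlated comparisons.

    Parameters
    ----------
    k : number of treatment-control comparisons (>= 1).
    info_fractions : strictly increasing, ending at 1.
    alpha : one-sided familywise level.
    spending : spending-function identifier.
    loadings : per-arm one-factor loadings (cross-arm correlation is the
        product); default sqrt(1/2), the equal-allocation equal-variance case.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    fr = tuple(round(float(t), 12) for t in np.atleast_1d(info_fractions))
    if any(b <= a for a, b in zip(fr, fr[1:])) or abs(fr[-1] - 1.0) > 1e-9 \
            or fr[0] <= 0:
        raise ValueError("info fractions must increase strictly to 1")
    if loadings is None:
        loadings = (round(np.sqrt(0.5), 12),) * k
    else:
        loadings = tuple(round(float(x), 12) for x in np.broadcast_to(
            np.asarray(loadings, float), (k,)))
    if spending not in _SPENDING:
        raise ValueError("unknown spending function %r" % (spending,))
    return _boundaries_cached(k, fr, float(alpha), spending, loadings)


def max_stat_exit_prob(boundaries: GSBoundaries, mean_shift=None,
                       loadings=None) -> np.ndarray:
    """Per-stage first-crossing probabilities of the max statistic.

    ``mean_shift`` is delta_i * sqrt(I_iJ) per arm (the Wald-scale drift at
    full information); zero recovers the spent alpha_j.  The returned vector
    plus the never-crossing probability sums to one.
    """
    k = boundaries.n_comparisons
    fr = np.asarray(boundaries.info_fractions)
    a = np.full(k, np.sqrt(0.5)) if loadings is None \
        else np.broadcast_to(np.asarray(loadings, float), (k,))
    inc = np.diff(np.r_[0.0, fr])
    inc_sd = np.sqrt(inc)[:, None] * np.ones((1, k))
    shift = np.zeros(k) if mean_shift is None \
        else np.broadcast_to(np.asarray(mean_shift, float), (k,))
    inc_mean = inc[:, None] * shift[None, :]
    upper = np.array([[w * np.sqrt(fr[j])] * k
                      for j, w in enumerate(boundaries.wald)])
    return path_exit_probs(upper, inc_sd, a, inc_mean)


def t_adjust_boundary(b, est_info, df):
    """Small-sample adjustment b* = sqrt(I) * T_df^{-1}(Phi(b / sqrt(I))).

    Maps a score-scale boundary through the Student quantile so that Wald
    statistics built from estimated information can be monitored without
    type-1 error inflation; b* -> b as df -> infinity.
    """
    est_info = np.asarray(est_info, dtype=float)
    if np.any(est_info <= 0):
        raise ValueError("estimated information must be positive")
    df = np.asarray(df, dtype=float)
    if np.any(df < 1):
        raise ValueError("degrees of freedom must be >= 1")
    s = np.sqrt(est_info)
    return s * t_dist.ppf(norm.cdf(np.asarray(b, dtype=float) / s), df)
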