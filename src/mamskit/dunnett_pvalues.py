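"""Multiplicity-adjusted p-values for intersection hypotheses.

For an intersection hypothesis H_0I over a subset I of treatment arms, the
stage-j adjusted p-value is computed from the *incremental* stage data.  The
exact Dunnett p-value is

    p_I(j) = P_{H0I}( max T_I(j) >= max t_I(j) ),

where T_I(j) is central multivariate t with n_0(j) + sum_{i in I} n_i(j)
- ||I|| - 1 degrees of freedom and product correlation determined by the
allocation ratios (0.5 under equal allocation).  Nonparametric Bonferroni
and Simes adjustments of marginal one-sided two-sample t p-values are
provided as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist

from ._quad import onefactor_t_lower
from .design import DesignSpec
from .observation import StageObservation

__all__ = ["StagePValues", "dunnett_p", "bonferroni_p", "simes_p",
           "stage_pvalue"]


def allocation_loadings(allocation) -> np.ndarray:
    """One-factor loadings sqrt(lambda_i / (1 + lambda_i)) implied by the
    treatment:control allocation ratios (equal response variances)."""
    lam = np.asarray(allocation, dtype=float)
    return np.sqrt(lam / (1.0 + lam))


def dunnett_p(max_t: float, k: int, df: float, loadings=None) -> float:
    """Exact one-sided Dunnett p-value: 1 - P(all of a central k-variate t
    with the given correlation fall below ``max_t``).

    ``df=inf`` gives the known-variance (multivariate normal) version; k = 1
    reduces to the univariate one-sided t (or z) p-value.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if loadings is None:
        loadings = np.full(k, np.sqrt(0.5))
    else:
        loadings = np.broadcast_to(np.asarray(loadings, float), (k,))
    if np.isneginf(max_t):
        return 1.0
    if np.isposinf(max_t):
        return 0.0
    return float(1.0 - onefactor_t_lower(np.full(k, float(max_t)),
                                         loadings, df))


def bonferroni_p(pvals) -> float:
    """min(1, ||I|| * min p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(min(1.0, p.size * p.min()))


def simes_p(pvals) -> float:
    """min_r ||I|| * p_(r) / r over the ordered p-values."""
    p = np.sort(np.asarray(pvals, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value set")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    r = np.arange(1, p.size + 1)
    return float(min(1.0, (p.size * p / r).min()))


@dataclass(frozen=True)
class StagePValues:
    subset: tuple
    stage: int
    t_stats: np.ndarray      # per-arm incremental t statistics (subset order)
    p_adjusted: float
    method: str
    df: float


def _marginal_t_pvalues(obs: StageObservation, arms, stage: int) -> np.ndarray:
    """One-sided pooled-variance two-sample t p-values, incremental data."""
    j = stage - 1
    n = obs.inc_n[j]
    m = obs.inc_mean[j]
    ss = obs.inc_ss[j]
    out = []
    for i in arms:
        df = n[0] + n[i] - 2
        sp2 = (ss[0] + ss[i]) / df
        tval = (m[i] - m[0]) / np.sqrt(sp2 * (1.0 / n[0] + 1.0 / n[i]))
        out.append(float(t_dist.sf(tval, df)))
    return np.array(out)


def stage_pvalue(spec: DesignSpec, obs: StageObservation, subset, stage: int,
                 method: str = "dunnett", selected=None,
                 known_variances=None) -> StagePValues:
    """Adjusted p-value for H_0I from the stage-``stage`` incremental data.

    From the second stage onward the statistic is restricted to
    I_S = I intersect S, the arms carried forward; an empty I_S yields the
    conservative p = 1 (this never blocks rejection of a selected arm, since
    every intersection containing a selected arm has it in I_S).
    """
    subset = tuple(sorted(subset))
    if not subset:
        raise ValueError("empty subset")
    active = subset
    if stage >= 2 and selected is not None:
        active = tuple(i for i in subset if i in set(selected))
        if not active:
            return StagePValues(subset, stage, np.array([]), 1.0, method,
                                np.nan)
    j = stage - 1
    n = obs.inc_n[j]
    wald = obs.wald(stage, incremental=True, known_variances=known_variances)
    t_stats = wald[[i - 1 for i in active]]
    if method in ("bonferroni", "simes"):
        marg = _marginal_t_pvalues(obs, active, stage)
        p = bonferroni_p(marg) if method == "bonferroni" else simes_p(marg)
        return StagePValues(subset, stage, t_stats, p, method, np.nan)
    if method != "dunnett":
        raise ValueError("unknown adjustment method %r" % (method,))
    df = np.inf if known_variances is not None else \
        n[0] + sum(n[i] for i in active) - len(active) - 1
    loadings = allocation_loadings([spec.allocation[i - 1] for i in active])
    p = dunnett_p(float(np.max(t_stats)), len(active), df, loadings)
    return StagePValues(subset, stage, t_stats, p, method, float(df))
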