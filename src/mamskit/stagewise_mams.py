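"""Stage-wise MAMS: inverse-normal combination closed testing.

Each intersection hypothesis H_0I is tested by combining its stage-wise
multiplicity-adjusted p-values with prespecified inverse-normal weights,

    Z_Ij = sum_{k<=j} h_k Phi^{-1}(1 - p_I(k)) / sqrt(sum_{k<=j} h_k^2),

and monitoring Z_Ij against the *two-arm* group-sequential boundaries c_j
(k = 1 in :func:`mamskit.boundaries.max_stat_boundaries`): the c_j protect
only the multiplicity of looking at the same hypothesis repeatedly; the
cross-arm multiplicity is absorbed by the adjusted p-values.  An elementary
hypothesis H_0i is rejected at stage j when Z_Ij >= c_j for every subset I
of the full arm set containing i (closed testing); the trial then stops.
Because the weights are fixed in advance, each Z_Ij is standard normal
under H_0I even when stage-2 sample sizes are chosen after seeing stage-1
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import norm

from .boundaries import GSBoundaries, max_stat_boundaries
from .design import DesignSpec
from .dunnett_pvalues import stage_pvalue
from .observation import StageObservation

__all__ = ["combine", "CombinationState", "stagewise_closed_test",
           "StagewiseResult", "all_subsets"]

_P_CLIP = 1e-15


def all_subsets(n_arms: int):
    """All nonempty subsets of {1..D}, smallest last for readable output."""
    arms = range(1, n_arms + 1)
    out = []
    for r in range(n_arms, 0, -1):
        out.extend(combinations(arms, r))
    return out


def combine(p_list, weights) -> float:
    """Normalized inverse-normal combination of stage-wise p-values.

    Combines the first len(p_list) stages with weights h_k, renormalized so
    the statistic is standard normal under the null at every interim:
    Z = sum h_k Phi^{-1}(1 - p_k) / sqrt(sum h_k^2).  p-values are clipped
    to [1e-15, 1 - 1e-15] before the quantile transform.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    h = np.asarray(weights, dtype=float)[:p.size]
    if h.size != p.size:
        raise ValueError("fewer weights than stages")
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return float(h @ norm.ppf(1.0 - p) / np.sqrt(h @ h))


@dataclass
class CombinationState:
    """Trace of one intersection hypothesis through the stage-wise test."""
    subset: tuple
    p_values: list = field(default_factory=list)   # adjusted p per stage
    z_values: list = field(default_factory=list)   # combined Z per stage
    rejected_at: int | None = None


@dataclass
class StagewiseResult:
    rejected: set                  # elementary arms rejected
    rejected_at: dict              # arm -> stage
    stopped_at: int                # stage the trial stopped (J if it ran out)
    records: dict                  # subset -> CombinationState
    boundaries: GSBoundaries


def stagewise_closed_test(spec: DesignSpec, obs: StageObservation,
                          selected=None, method: str = "dunnett",
                          boundaries: GSBoundaries = None,
                          known_variances=None) -> StagewiseResult:
    """Run the stage-wise closed test over the observed stages.

    ``selected`` is the set of arms carried into stage 2 (all arms by
    default); stage >= 2 p-values restrict to I intersect selected while
    stage-1 components always retain the full subset.  Stops at the first
    stage with an elementary rejection.
    """
    J_obs = obs.n_stages_observed
    if J_obs > spec.n_stages:
        raise ValueError("observed more stages than the design specifies")
    if boundaries is None:
        boundaries = max_stat_boundaries(1, spec.info_fractions,
                                         spec.one_sided_alpha, spec.spending)
    c = boundaries.wald
    subsets = all_subsets(spec.n_arms)
    records = {I: CombinationState(I) for I in subsets}
    rejected, rejected_at = set(), {}
    stopped_at = J_obs
    for stage in range(1, J_obs + 1):
        for I in subsets:
            rec = records[I]
            sp = stage_pvalue(spec, obs, I, stage, method=method,
                              selected=None if stage == 1 else selected,
                              known_variances=known_variances)
            rec.p_values.append(sp.p_adjusted)
            rec.z_values.append(combine(rec.p_values, spec.weights))
        for I in subsets:
            if records[I].rejected_at is None and \
                    records[I].z_values[-1] >= c[stage - 1]:
                records[I].rejected_at = stage
        newly = set()
        for i in range(1, spec.n_arms + 1):
            if i in rejected:
                continue
            if all(records[I].rejected_at is not None
                   for I in subsets if i in I):
                newly.add(i)
        if newly:
            rejected |= newly
            for i in newly:
                rejected_at[i] = stage
            stopped_at = stage
            break
    return StagewiseResult(rejected=rejected, rejected_at=rejected_at,
                           stopped_at=stopped_at, records=records,
                           boundaries=boundaries)
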