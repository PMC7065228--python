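"""Cumulative MAMS: adaptive max-score closed testing.

Each intersection hypothesis H_0I is monitored through the maximum of the
cumulative score statistics over I against multiplicity-adjusted
group-sequential boundaries (Step 1).  After an interim adaptation --
dropping arms and/or changing stage-2 sample sizes while keeping the
allocation ratios -- the later boundaries are recomputed (Step 2) so that
the conditional probability, given the stage-1 scores, of crossing with the
*adapted* design over the *selected* subset I_S equals the conditional
crossing probability of the original design over the full subset I
(Mueller-Schaefer conditional error principle).  H_0i is rejected once every
intersection containing arm i has been rejected; the trial stops at the
first stage with an elementary rejection.

Conditioning on the stage-1 scores is what makes this cheap: the increments
are independent of stage 1 and one-factor correlated across arms, so every
conditional crossing probability is a one- or two-dimensional smooth
integral (see :mod:`mamskit._quad`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ._quad import onefactor_lower, path_lower
from .boundaries import max_stat_boundaries, t_adjust_boundary
from .design import DesignSpec
from .dunnett_pvalues import allocation_loadings
from .observation import StageObservation
from .stagewise_mams import all_subsets

__all__ = ["IntersectionRecord", "conditional_error", "recompute_boundary",
           "cumulative_closed_test", "CumulativeResult"]

_RESIDUAL_TOL = 1e-6


@dataclass
class IntersectionRecord:
    """One subset's journey through the adaptive closed test."""
    subset: tuple
    wald_bounds: tuple                 # design Wald-scale constants e_j(k)
    conditional_error: float | None = None     # stage-2 A_I given stage-1 data
    conditional_error_3: float | None = None   # stage-3 analogue (J = 3)
    recomputed: dict = field(default_factory=dict)  # stage -> b*_Ij (score)
    residual: float = 0.0              # |LHS - RHS| of the preservation equation
    rejected_at: int | None = None


@dataclass
class CumulativeResult:
    rejected: set
    rejected_at: dict
    stopped_at: int
    records: dict                      # subset -> IntersectionRecord


def conditional_error(w1, b2, inc_sd, loadings) -> float:
    """P0(max_g (w_g1 + V_g(2)) >= b2_g | w_1) for one-factor increments.

    ``w1`` are the observed stage-1 scores of the arms in I, ``b2`` the
    stage-2 score boundary (scalar or per arm), ``inc_sd`` the increment
    standard deviations sqrt(I_g(2)).
    """
    w1 = np.atleast_1d(np.asarray(w1, dtype=float))
    upper = np.broadcast_to(np.asarray(b2, dtype=float), w1.shape) - w1
    return float(1.0 - onefactor_lower(upper, loadings, sd=inc_sd))


def _cond_noncross(w1, bounds, inc_sd, loadings):
    """P0(all arms below ``bounds[j]`` at every later stage | w_1);
    bounds/inc_sd have shape (J_later, k)."""
    bounds = np.atleast_2d(bounds)
    upper = bounds - np.atleast_1d(w1)[None, :]
    if np.any(upper[0] <= -8 * np.max(inc_sd)):
        return 0.0
    # exact inner bivariate rectangles make modest outer grids sufficient
    return path_lower(upper, np.atleast_2d(inc_sd), loadings,
                      n_gh=24, n_gl=24)


def recompute_boundary(w1_sel, target, inc_sd_new, loadings_sel,
                       hint: float = None) -> tuple:
    """Solve P0(max_g (w_g1 + V*_g(2)) >= b* | w_1) = target for b*.

    Returns (b*, residual).  ``target`` is the conditional error of the
    original design; the root is found by Brent's method on an expanding
    bracket.  target <= 0 gives an infinite boundary (nothing to spend).
    """
    w1_sel = np.atleast_1d(np.asarray(w1_sel, dtype=float))
    if target <= 1e-14:
        return np.inf, 0.0
    if target >= 1.0:
        return -np.inf, 0.0
    inc_sd_new = np.asarray(inc_sd_new, dtype=float)

    def f(b):
        return conditional_error(w1_sel, b, inc_sd_new, loadings_sel) - target

    center = float(np.max(w1_sel)) if hint is None else hint
    span = 1.0 + float(np.max(inc_sd_new))
    lo, hi = center - 8 * span, center + 10 * span
    while f(lo) < 0 and lo > center - 200 * span:
        lo -= 8 * span
    while f(hi) > 0 and hi < center + 200 * span:
        hi += 8 * span
    root = brentq(f, lo, hi, xtol=1e-10)
    return float(root), abs(f(root))


def _recompute_stage3(w1_sel, b2_star, target, inc_sd_new, loadings_sel):
    """Solve for b*_3: conditional P0(no stage-2 crossing, stage-3 crossing)
    given stage-1 data must equal the original design's (J = 3)."""
    if target <= 1e-14:
        return np.inf, 0.0
    w1_sel = np.atleast_1d(w1_sel)
    k = w1_sel.size

    def f(b3):
        u = np.array([np.full(k, b2_star), np.full(k, b3)])
        keep2 = _cond_noncross(w1_sel, u[:1], inc_sd_new[:1], loadings_sel)
        keep23 = _cond_noncross(w1_sel, u, inc_sd_new, loadings_sel)
        return (keep2 - keep23) - target

    center = max(float(np.max(w1_sel)), b2_star)
    span = 1.0 + float(np.max(inc_sd_new))
    lo, hi = center - 8 * span, center + 10 * span
    while f(lo) < 0 and lo > center - 200 * span:
        lo -= 8 * span
    while f(hi) > 0 and hi < center + 200 * span:
        hi += 8 * span
    root = brentq(f, lo, hi, xtol=1e-10)
    return float(root), abs(f(root))


def _pair_info(v0, vi, n0, ni):
    """(sigma_0^2/n_0 + sigma_i^2/n_i)^{-1} elementwise; 0 where n_i == 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 / (v0 / n0 + vi / ni)
    return np.where((ni > 0) & (n0 > 0), out, 0.0)


def cumulative_closed_test(spec: DesignSpec, obs: StageObservation,
                           selected=None, use_t_adjustment: bool = True,
                           known_variances=None) -> CumulativeResult:
    """Run the adaptive cumulative MAMS closed test over the observed stages.

    ``selected`` is the arm subset carried past stage 1 (default: all).
    Sample-size changes are read off the realized incremental sample sizes
    in ``obs``; whenever the selection or the realized schedule differs from
    the plan, the stage >= 2 boundaries of every live intersection are
    recomputed to preserve its conditional error.  ``known_variances``
    switches to exact known-variance monitoring (no t adjustment).
    """
    D, J = spec.n_arms, spec.n_stages
    J_obs = obs.n_stages_observed
    if J_obs > J:
        raise ValueError("observed more stages than the design specifies")
    if J > 3:
        raise NotImplementedError("cumulative MAMS implemented for J <= 3")
    selected = set(range(1, D + 1)) if selected is None else set(selected)
    lam = np.asarray(spec.allocation)
    loadings = allocation_loadings(lam) if known_variances is None else None
    known = known_variances is not None
    if known:
        v = np.asarray(known_variances, dtype=float)
        loadings = np.sqrt(v[0] * np.array(
            [1.0 / (v[0] + v[i] / lam[i - 1]) for i in range(1, D + 1)]))

    subsets = all_subsets(D)
    records = {I: IntersectionRecord(
        I, max_stat_boundaries(len(I), spec.info_fractions,
                               spec.one_sided_alpha, spec.spending,
                               loadings=[loadings[g - 1] for g in I]).wald)
        for I in subsets}

    planned_n = spec.arm_stage_sizes.astype(float)      # (J, D+1) cumulative
    real_cum_n = obs.cum_n                              # realized cumulative

    # interim variance estimates fix the conditional-error information scale
    def variances_at(stage):
        if known:
            return v
        return obs.truncated(stage).cum_var()[stage - 1]

    def crossing(I, stage, bounds_score, w, info_hat, dfs):
        """Did any selected arm of I cross its score-scale bound?"""
        out = False
        for g in I:
            b = bounds_score[g]
            if use_t_adjustment and not known:
                b = float(t_adjust_boundary(b, info_hat[g - 1], dfs[g - 1]))
            if w[g - 1] >= b:
                out = True
        return out

    rejected, rejected_at = set(), {}
    stopped_at = J_obs
    adapted = False
    v_int = None
    for stage in range(1, J_obs + 1):
        w = obs.score(stage, known_variances=known_variances)
        info_hat = obs.est_info(stage, known_variances=known_variances)
        n_now = real_cum_n[stage - 1]
        dfs = np.array([n_now[0] + n_now[g] - 1 for g in range(1, D + 1)])
        if stage == 2:
            # adaptation happened at the end of stage 1
            v_int = variances_at(1)
            adapted = (selected != set(range(1, D + 1))) or not np.array_equal(
                real_cum_n[1:J_obs], planned_n[1:J_obs, :])
            if adapted:
                _recompute_all(spec, obs, records, selected, v_int, loadings,
                               planned_n, real_cum_n, J)
        for I in subsets:
            rec = records[I]
            if rec.rejected_at is not None:
                continue
            live = [g for g in I if stage == 1 or g in selected]
            if not live:
                continue
            if adapted and stage >= 2:
                b_star = rec.recomputed.get(stage)
                if b_star is None:
                    continue
                bounds = {g: b_star for g in live}
            else:
                e = rec.wald_bounds[stage - 1]
                bounds = {g: e * np.sqrt(info_hat[g - 1]) for g in live}
            if crossing(live, stage, bounds, w, info_hat, dfs):
                rec.rejected_at = stage
        newly = set()
        for i in range(1, D + 1):
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
    return CumulativeResult(rejected=rejected, rejected_at=rejected_at,
                            stopped_at=stopped_at, records=records)


def _recompute_all(spec, obs, records, selected, v_int, loadings,
                   planned_n, real_cum_n, J):
    """Recompute every live intersection's later boundaries by conditional
    error preservation, on the interim estimated-information scale."""
    D = spec.n_arms
    w1 = obs.score(1, known_variances=v_int)
    arms = np.arange(1, D + 1)
    # planned cumulative and incremental pair information, interim variances
    info_plan = np.array([_pair_info(v_int[0], v_int[arms], planned_n[j, 0],
                                     planned_n[j, arms]) for j in range(J)])
    inc_plan = np.array([_pair_info(
        v_int[0], v_int[arms],
        planned_n[j, 0] - planned_n[j - 1, 0] if j else planned_n[0, 0],
        planned_n[j, arms] - planned_n[j - 1, arms] if j
        else planned_n[0, arms]) for j in range(J)])
    # realized incremental information for the selected arms
    inc_real = np.array([_pair_info(
        v_int[0], v_int[arms],
        real_cum_n[j, 0] - real_cum_n[j - 1, 0],
        real_cum_n[j, arms] - real_cum_n[j - 1, arms])
        for j in range(1, real_cum_n.shape[0])])
    for I, rec in records.items():
        if rec.rejected_at is not None:
            continue
        gi = np.array(I) - 1
        a_I = loadings[gi]
        I_S = [g for g in I if g in selected]
        # original design: conditional exit probabilities given stage-1 scores
        b_score = np.array([rec.wald_bounds[j] * np.sqrt(info_plan[j, gi])
                            for j in range(J)])          # (J, |I|)
        sd_plan = np.sqrt(inc_plan[1:, gi])              # (J-1, |I|)
        A2 = conditional_error(w1[gi], b_score[1], sd_plan[0], a_I)
        rec.conditional_error = A2
        if J == 3:
            keep2 = _cond_noncross(w1[gi], b_score[1:2], sd_plan[:1], a_I)
            keep23 = _cond_noncross(w1[gi], b_score[1:], sd_plan, a_I)
            rec.conditional_error_3 = max(keep2 - keep23, 0.0)
        if not I_S:
            continue     # conditional error unspendable; never rejectable
        si = np.array(I_S) - 1
        a_S = loadings[si]
        sd_real = np.sqrt(inc_real[:, si])
        b2_star, res2 = recompute_boundary(w1[si], A2, sd_real[0], a_S)
        rec.recomputed[2] = b2_star
        rec.residual = res2
        if J == 3 and inc_real.shape[0] >= 2:
            b3_star, res3 = _recompute_stage3(
                w1[si], b2_star, rec.conditional_error_3, sd_real, a_S)
            rec.recomputed[3] = b3_star
            rec.residual = max(rec.residual, res3)
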