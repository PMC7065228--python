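"""Patient-level Monte-Carlo engine for MAMS operating characteristics.

Each replicate draws normal patient responses stage by stage, applies the
interim decision rules of the protocol -- early efficacy stopping, dropping
of arms whose interim effect estimate falls below the selection threshold,
reallocation of the dropped arms' unspent enrollment -- and runs one or more
testing procedures on the *same* data.  Evaluating competing procedures on
shared replicates (common random numbers) makes power differences far more
precise than independent simulations.

Supported methods: "cumulative" (adaptive max-score closed test with
conditional-error boundary recomputation), "stagewise_dunnett" /
"stagewise_simes" / "stagewise_bonferroni" (inverse-normal combination
closed tests), and "single_stage_dunnett" (the fixed-sample reference
design, simulated from an independent substream since it follows a
different enrollment plan).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .analytic_power import dunnett_critical_value
from .cumulative_mams import cumulative_closed_test
from .design import DesignSpec
from .observation import StageObservation
from .stagewise_mams import stagewise_closed_test

__all__ = ["SelectionRule", "TrialOutcome", "OperatingCharacteristics",
           "simulate_trial", "reallocate", "operating_characteristics",
           "METHODS"]

METHODS = ("cumulative", "stagewise_dunnett", "stagewise_simes",
           "stagewise_bonferroni", "single_stage_dunnett")


@dataclass(frozen=True)
class SelectionRule:
    """Drop arm i at the end of stage 1 iff deltahat_i1 < threshold
    (response units); -inf disables dropping."""
    threshold: float = -math.inf


@dataclass
class TrialOutcome:
    rejected: set
    stopped_at: int
    total_n: int
    dropped: set


@dataclass
class OperatingCharacteristics:
    """Monte-Carlo estimates over ``n_replicates`` simulated trials."""
    method: str
    n_replicates: int
    power: float                # P(reject at least one elementary H0)
    power_se: float
    fwer: float                 # P(reject at least one true null)
    fwer_se: float
    arm_rejection_rates: np.ndarray
    asn: float                  # mean enrolled total at stopping
    asn_se: float
    stage_stop_freq: np.ndarray

    def as_row(self) -> dict:
        row = {"method": self.method, "n_replicates": self.n_replicates,
               "power": self.power, "power_se": self.power_se,
               "fwer": self.fwer, "fwer_se": self.fwer_se,
               "asn": self.asn, "asn_se": self.asn_se}
        row.update({"reject_arm_%d" % (i + 1): r
                    for i, r in enumerate(self.arm_rejection_rates)})
        row.update({"stop_stage_%d" % (j + 1): f
                    for j, f in enumerate(self.stage_stop_freq)})
        return row


def _largest_remainder(total: int, weights) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``,
    exact sum preserved (largest-remainder method, ties to lower index)."""
    w = np.asarray(weights, dtype=float)
    if total == 0 or w.sum() == 0:
        return np.zeros(w.size, dtype=int)
    quota = total * w / w.sum()
    base = np.floor(quota).astype(int)
    short = int(total - base.sum())
    if short > 0:
        order = np.lexsort((np.arange(w.size), -(quota - base)))
        base[order[:short]] += 1
    return base


def reallocate(spec: DesignSpec, dropped, rule: str = None) -> np.ndarray:
    """Realized incremental sample sizes for stages 2..J after dropping.

    Returns an array of shape (J-1, D+1), column 0 the control arm.  Under
    "proportional_upscaling" the dropped arms' unspent enrollment is
    redistributed over the continuing arms (control included) proportionally
    to the allocation ratios, preserving the planned total exactly
    (largest-remainder integer rounding); under "none" it is simply not
    enrolled.  Each continuing arm's bonus is spread over its remaining
    stages proportionally to the planned increments.
    """
    rule = spec.reallocation_rule if rule is None else rule
    cum = spec.arm_stage_sizes
    inc = np.diff(cum, axis=0).astype(int)          # (J-1, D+1)
    dropped = set(dropped)
    if not dropped or rule == "none":
        out = inc.copy()
        for g in dropped:
            out[:, g] = 0
        return out
    if rule != "proportional_upscaling":
        raise ValueError("unknown reallocation rule %r" % (rule,))
    continuing = [0] + [i for i in range(1, spec.n_arms + 1)
                        if i not in dropped]
    if continuing == [0]:
        # everything dropped: nothing to upscale toward; control unchanged
        out = inc.copy()
        out[:, 1:] = 0
        return out
    pool = int(sum(inc[:, g].sum() for g in dropped))
    lam = np.r_[1.0, np.asarray(spec.allocation)]
    bonus = _largest_remainder(pool, [lam[c] for c in continuing])
    out = inc.copy()
    for g in dropped:
        out[:, g] = 0
    for c, extra in zip(continuing, bonus):
        out[:, c] = inc[:, c] + _largest_remainder(int(extra), inc[:, c])
    return out


def _draw_stage(rng, sizes, means, sds):
    """Per-arm incremental summaries (n, mean, ss) for one stage."""
    n = np.asarray(sizes, dtype=int)
    mean = np.full(n.size, np.nan)
    ss = np.zeros(n.size)
    for i, ni in enumerate(n):
        if ni > 0:
            x = rng.normal(means[i], sds[i], size=ni)
            mean[i] = x.mean()
            ss[i] = np.sum((x - mean[i]) ** 2)
    return n.astype(float), mean, ss


def _single_stage_dunnett(spec, delta, rng, known_variance) -> TrialOutcome:
    """Fixed-sample Dunnett reference design at the planned final sizes."""
    D = spec.n_arms
    sds = np.sqrt(np.asarray(spec.variances))
    means = np.r_[0.0, np.asarray(delta)]
    sizes = spec.arm_stage_sizes[-1]
    n, mean, ss = _draw_stage(rng, sizes, means, sds)
    obs = StageObservation(n[None, :], mean[None, :], ss[None, :])
    kv = spec.variances if known_variance else None
    t_stats = obs.wald(1, known_variances=kv)
    df = np.inf if known_variance else float(n.sum() - D - 1)
    c = dunnett_critical_value(D, spec.one_sided_alpha, df)
    rejected = {i + 1 for i in range(D) if t_stats[i] >= c}
    return TrialOutcome(rejected=rejected, stopped_at=1,
                        total_n=int(n.sum()), dropped=set())


def simulate_trial(spec: DesignSpec, delta, methods=("cumulative",),
                   rng=None, seed=None, rule: SelectionRule = None,
                   use_t_adjustment: bool = True,
                   known_variance: bool = False) -> dict:
    """Simulate one trial and apply each requested method to the same data.

    Returns {method: TrialOutcome}.  ``delta`` holds the true effects versus
    control; response variances come from the design.  The selection rule
    defaults to the design's threshold.  A fixed seed (or generator state)
    makes the outcome bit-identical on re-run.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    methods = tuple(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError("unknown methods: %s" % sorted(unknown))
    delta = np.broadcast_to(np.asarray(delta, dtype=float), (spec.n_arms,))
    rule = SelectionRule(spec.selection_threshold) if rule is None else rule
    sds = np.sqrt(np.asarray(spec.variances))
    means = np.r_[0.0, delta]
    kv = spec.variances if known_variance else None

    out = {}
    if "single_stage_dunnett" in methods:
        child = np.random.default_rng(int(rng.integers(0, 2 ** 31 - 1)))
        out["single_stage_dunnett"] = _single_stage_dunnett(
            spec, delta, child, known_variance)
    seq_methods = [m for m in methods if m != "single_stage_dunnett"]
    if not seq_methods:
        return out

    # stage 1 at the planned sizes
    rows = [_draw_stage(rng, spec.arm_stage_sizes[0], means, sds)]
    obs1 = StageObservation(rows[0][0][None, :], rows[0][1][None, :],
                            rows[0][2][None, :])
    delta_hat1 = obs1.delta_hat(1)
    dropped = {i + 1 for i in range(spec.n_arms)
               if delta_hat1[i] < rule.threshold}
    selected = set(range(1, spec.n_arms + 1)) - dropped

    if spec.n_stages > 1 and selected:
        sched = reallocate(spec, dropped)
        for j in range(spec.n_stages - 1):
            rows.append(_draw_stage(rng, sched[j], means, sds))
    obs = StageObservation(np.stack([r[0] for r in rows]),
                           np.stack([r[1] for r in rows]),
                           np.stack([r[2] for r in rows]))
    totals = obs.cum_n.sum(axis=1)

    for m in seq_methods:
        if m == "cumulative":
            res = cumulative_closed_test(
                spec, obs, selected=selected,
                use_t_adjustment=use_t_adjustment, known_variances=kv)
        else:
            res = stagewise_closed_test(
                spec, obs, selected=selected,
                method=m.removeprefix("stagewise_"), known_variances=kv)
        stopped = res.stopped_at
        out[m] = TrialOutcome(rejected=res.rejected, stopped_at=stopped,
                              total_n=int(totals[stopped - 1]),
                              dropped=dropped)
    return out


def operating_characteristics(spec: DesignSpec, delta,
                              methods=("cumulative",), n_reps: int = 10000,
                              seed: int = 0, rule: SelectionRule = None,
                              use_t_adjustment: bool = True,
                              known_variance: bool = False,
                              progress=None) -> dict:
    """Monte-Carlo operating characteristics over independent substreams.

    Returns {method: OperatingCharacteristics}.  Power is global (reject at
    least one elementary hypothesis); FWER counts rejections of true nulls
    (delta_i <= 0).  Replicates use spawned seed sequences, so results do
    not depend on evaluation order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    delta = np.broadcast_to(np.asarray(delta, dtype=float), (spec.n_arms,))
    true_null = {i + 1 for i in range(spec.n_arms) if delta[i] <= 0}
    methods = tuple(methods)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    any_rej = {m: 0 for m in methods}
    null_rej = {m: 0 for m in methods}
    arm_rej = {m: np.zeros(spec.n_arms) for m in methods}
    tot = {m: [] for m in methods}
    stops = {m: np.zeros(spec.n_stages) for m in methods}
    for r in range(n_reps):
        rng = np.random.default_rng(children[r])
        res = simulate_trial(spec, delta, methods=methods, rng=rng, rule=rule,
                             use_t_adjustment=use_t_adjustment,
                             known_variance=known_variance)
        for m, oc in res.items():
            if oc.rejected:
                any_rej[m] += 1
            if oc.rejected & true_null:
                null_rej[m] += 1
            for i in oc.rejected:
                arm_rej[m][i - 1] += 1
            tot[m].append(oc.total_n)
            stops[m][oc.stopped_at - 1] += 1
        if progress is not None and (r + 1) % 1000 == 0:
            progress(r + 1, n_reps)
    out = {}
    for m in methods:
        p = any_rej[m] / n_reps
        f = null_rej[m] / n_reps
        totals = np.asarray(tot[m], dtype=float)
        out[m] = OperatingCharacteristics(
            method=m, n_replicates=n_reps,
            power=p, power_se=math.sqrt(p * (1 - p) / n_reps),
            fwer=f, fwer_se=math.sqrt(f * (1 - f) / n_reps),
            arm_rejection_rates=arm_rej[m] / n_reps,
            asn=float(totals.mean()),
            asn_se=float(totals.std(ddof=1) / math.sqrt(n_reps)),
            stage_stop_freq=stops[m] / n_reps)
    return out
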