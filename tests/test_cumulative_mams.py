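import numpy as np
import pytest

from mamskit.boundaries import max_stat_boundaries
from mamskit.covariance import increment_information, information
from mamskit.cumulative_mams import (conditional_error,
                                     cumulative_closed_test,
                                     recompute_boundary)
from mamskit.design import DesignSpec, socrates_design
from mamskit.observation import StageObservation
from mamskit.simulator import reallocate, simulate_trial
from mamskit.stagewise_mams import all_subsets

A = np.sqrt(0.5)


class TestConditionalError:
    def test_infinite_boundary(self):
        assert conditional_error([0.0, 0.0], np.inf, [1.0, 1.0],
                                 [A, A]) == 0.0

    def test_monotone_in_boundary(self):
        w = np.array([0.5, -0.2])
        vals = [conditional_error(w, b, [1.0, 1.0], [A, A])
                for b in (0.0, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(vals) < 0)

    def test_matches_monte_carlo(self, socrates2, rng):
        """Conditional crossing probability of the stage-2 max given zero
        stage-1 scores agrees with direct simulation of the increments."""
        info2 = increment_information(socrates2, 1, 2)
        sd = np.sqrt(info2)
        b2 = 2.2 * np.sqrt(information(socrates2, 1, 2))
        got = conditional_error([0.0, 0.0], b2, [sd, sd], [A, A])
        reps = 1_000_000
        zf = rng.standard_normal(reps)
        ze = rng.standard_normal((reps, 2))
        v = sd * (A * zf[:, None] + A * ze)
        emp = (v.max(axis=1) >= b2).mean()
        se = np.sqrt(emp * (1 - emp) / reps)
        assert got == pytest.approx(emp, abs=3 * se)


class TestRecomputeBoundary:
    def test_identity_without_adaptation(self):
        w1 = np.array([1.0, -0.5, 0.3])
        sd = np.array([2.0, 2.0, 2.0])
        b2 = 5.0
        target = conditional_error(w1, b2, sd, [A] * 3)
        b_star, resid = recompute_boundary(w1, target, sd, [A] * 3)
        assert b_star == pytest.approx(b2, abs=1e-7)
        assert resid < 1e-6

    def test_dropping_without_ssr_lowers_boundary(self, rng):
        """Restricting the stage-2 max to a subset while preserving the
        conditional error can only relax the boundary: b* <= b."""
        sd = np.full(3, 2.0)
        for _ in range(25):
            w1 = rng.normal(0, 2, size=3)
            b2 = 4.0
            target = conditional_error(w1, b2, sd, [A] * 3)
            for keep in ([0, 1], [2], [0]):
                b_star, resid = recompute_boundary(
                    w1[keep], target, sd[keep], [A] * len(keep))
                assert b_star <= b2 + 1e-7
                assert resid < 1e-6

    def test_unspendable_conditional_error(self):
        b_star, _ = recompute_boundary([0.0], 0.0, [1.0], [A])
        assert np.isinf(b_star)


def _adaptive_trial_records(spec, delta, seed, known=True):
    rng = np.random.default_rng(seed)
    sds = np.sqrt(np.asarray(spec.variances))
    means = np.r_[0.0, np.broadcast_to(delta, (spec.n_arms,))]
    s1 = [rng.normal(means[i], sds[i], spec.arm_stage_sizes[0][i])
          for i in range(spec.n_arms + 1)]
    obs1 = StageObservation.from_patient_data([s1])
    d1 = obs1.delta_hat(1)
    sel = {i + 1 for i in range(spec.n_arms) if d1[i] >= 0.0}
    if not sel:
        return None
    sched = reallocate(spec, set(range(1, spec.n_arms + 1)) - sel)
    stages = [s1]
    for j in range(spec.n_stages - 1):
        stages.append([rng.normal(means[i], sds[i], sched[j][i])
                       for i in range(spec.n_arms + 1)])
    obs = StageObservation.from_patient_data(stages)
    kv = spec.variances if known else None
    return cumulative_closed_test(spec, obs, selected=sel,
                                  use_t_adjustment=not known,
                                  known_variances=kv)


class TestClosedTest:
    def test_conditional_error_residuals_vanish(self, socrates2):
        """Every recomputed stage-2 boundary satisfies the conditional-error
        preservation equation to numerical tolerance."""
        checked = 0
        for seed in range(30):
            res = _adaptive_trial_records(socrates2, [0.0, 0.1, 0.187], seed)
            if res is None:
                continue
            for rec in res.records.values():
                if rec.recomputed:
                    assert rec.residual < 1e-6
                    checked += 1
        assert checked > 20

    def test_recomputed_at_most_original_without_ssr(self):
        """With dropped arms and no reallocation the recomputed boundary
        never exceeds the original one (efficiency gain of closed testing)."""
        spec = socrates_design(reallocation_rule="none")
        kv = spec.variances
        checked = 0
        for seed in range(40):
            res = _adaptive_trial_records(spec, [0.0, 0.0, 0.187], seed)
            if res is None:
                continue
            for I, rec in res.records.items():
                if 2 in rec.recomputed:
                    b_orig = rec.wald_bounds[1] * np.sqrt(
                        information(spec, I[0], 2))
                    assert rec.recomputed[2] <= b_orig + 1e-6
                    checked += 1
        assert checked > 20

    def test_consonance_without_adaptation(self, socrates2):
        """With no dropping and no reallocation, the closed test rejects the
        global null exactly when the max statistic crosses the D-comparison
        boundary, every monitored crossing is rejected (consonance), and the
        step-down structure never misses a crossing arm."""
        spec = socrates2
        kv = spec.variances
        gsb = max_stat_boundaries(3, spec.info_fractions,
                                  spec.one_sided_alpha)
        rng = np.random.default_rng(3)
        sds = np.sqrt(np.asarray(kv))
        means = np.r_[0.0, 0.15, 0.2, 0.25]
        for _ in range(60):
            stages = []
            for j, row in enumerate(spec.arm_stage_sizes):
                prev = spec.arm_stage_sizes[j - 1] if j else np.zeros(4, int)
                stages.append([rng.normal(means[i], sds[i], row[i] - prev[i])
                               for i in range(4)])
            obs = StageObservation.from_patient_data(stages)
            res = cumulative_closed_test(spec, obs, use_t_adjustment=False,
                                         known_variances=kv)
            w = {j: obs.score(j, known_variances=kv) for j in (1, 2)}
            info = {j: obs.est_info(j, known_variances=kv) for j in (1, 2)}
            crossed1 = w[1] >= gsb.wald[0] * np.sqrt(info[1])
            crossed2 = w[2] >= gsb.wald[1] * np.sqrt(info[2])
            if crossed1.any():
                expect = {i + 1 for i in range(3) if crossed1[i]}
            elif crossed2.any():
                expect = {i + 1 for i in range(3) if crossed2[i]}
            else:
                expect = set()
            # monitoring rejections are always recovered by the closed test,
            # and the closed test rejects someone iff the max crossed
            assert expect <= res.rejected
            assert bool(res.rejected) == bool(expect)

    def test_single_arm_reduces_to_group_sequential(self, rng):
        spec = DesignSpec(n_arms=1, n_stages=2, control_stage_sizes=(40, 80))
        gsb = max_stat_boundaries(1, spec.info_fractions, 0.025)
        data = [[rng.normal(0, 1, 40), rng.normal(0.8, 1, 40)],
                [rng.normal(0, 1, 40), rng.normal(0.8, 1, 40)]]
        obs = StageObservation.from_patient_data(data)
        res = cumulative_closed_test(spec, obs, use_t_adjustment=False,
                                     known_variances=(1.0, 1.0))
        w1 = obs.score(1, known_variances=(1.0, 1.0))[0]
        expect1 = w1 >= gsb.wald[0] * np.sqrt(information(spec, 1, 1))
        assert (res.rejected_at.get(1) == 1) == expect1

    def test_rejects_obvious_effect(self, socrates2):
        out = simulate_trial(socrates2, [5.2, 0.0, 0.0],
                             methods=("cumulative",), seed=5)
        assert 1 in out["cumulative"].rejected

    def test_three_stage_no_adaptation_reduces_to_monitoring(self, socrates3):
        """J=3 without selection: decisions match three-stage max-statistic
        monitoring (consonance extends to the multistage design)."""
        spec = socrates3
        kv = spec.variances
        gsb = max_stat_boundaries(3, spec.info_fractions,
                                  spec.one_sided_alpha)
        rng = np.random.default_rng(9)
        sds = np.sqrt(np.asarray(kv))
        means = np.r_[0.0, 0.1, 0.2, 0.3]
        for _ in range(20):
            stages = []
            for j, row in enumerate(spec.arm_stage_sizes):
                prev = spec.arm_stage_sizes[j - 1] if j else np.zeros(4, int)
                stages.append([rng.normal(means[i], sds[i], row[i] - prev[i])
                               for i in range(4)])
            obs = StageObservation.from_patient_data(stages)
            res = cumulative_closed_test(spec, obs, use_t_adjustment=False,
                                         known_variances=kv)
            expect = set()
            for j in (1, 2, 3):
                w = obs.score(j, known_variances=kv)
                info = obs.est_info(j, known_variances=kv)
                crossed = w >= gsb.wald[j - 1] * np.sqrt(info)
                if crossed.any():
                    expect = {i + 1 for i in range(3) if crossed[i]}
                    break
            assert expect <= res.rejected
            assert bool(res.rejected) == bool(expect)
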