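import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from mamskit._quad import bvn_lower, onefactor_lower
from mamskit.boundaries import (ld_obf_spending, max_stat_boundaries,
                                max_stat_exit_prob, t_adjust_boundary)

A = np.sqrt(0.5)


class TestSpending:
    def test_spends_all_alpha_at_the_end(self):
        assert ld_obf_spending(1.0, 0.025) == pytest.approx(0.025, abs=1e-12)

    def test_half_information_value(self):
        # 2 - 2 Phi(Phi^{-1}(0.9875) / sqrt(0.5))
        expect = 2 - 2 * norm.cdf(norm.ppf(0.9875) / np.sqrt(0.5))
        assert ld_obf_spending(0.5, 0.025) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(1.525e-3, abs=5e-6)

    def test_vanishes_at_zero(self):
        assert ld_obf_spending(1e-6, 0.025) < 1e-12

    def test_nondecreasing(self):
        t = np.linspace(0.05, 1.0, 30)
        f = [ld_obf_spending(x, 0.025) for x in t]
        assert np.all(np.diff(f) >= 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ld_obf_spending(0.0, 0.025)
        with pytest.raises(ValueError):
            ld_obf_spending(1.5, 0.025)


class TestMaxStatBoundaries:
    def test_two_arm_published_constants(self):
        gsb = max_stat_boundaries(1, (0.5, 1.0), 0.025)
        assert gsb.wald[0] == pytest.approx(2.9626, abs=5e-4)
        assert gsb.wald[1] == pytest.approx(1.9686, abs=5e-4)

    def test_exhausts_alpha(self):
        for k in (1, 2, 4):
            gsb = max_stat_boundaries(k, (0.5, 1.0), 0.025)
            assert sum(gsb.alpha_spent) == pytest.approx(0.025, abs=1e-10)
            exits = max_stat_exit_prob(gsb)
            assert exits.sum() == pytest.approx(0.025, abs=1e-4)

    def test_monotone_in_comparisons(self):
        w = [max_stat_boundaries(k, (0.5, 1.0), 0.025).wald for k in (1, 2, 3, 4)]
        for j in (0, 1):
            vals = [wk[j] for wk in w]
            assert np.all(np.diff(vals) > 0)

    def test_wald_decreasing_over_stages_obf(self):
        gsb = max_stat_boundaries(3, (1 / 3, 2 / 3, 1.0), 0.025)
        assert gsb.wald[0] > gsb.wald[1] > gsb.wald[2]

    def test_single_look_matches_monte_carlo(self, rng):
        """k=2, J=1, alpha=0.05: the critical value is the 95th percentile of
        the max of a correlation-0.5 bivariate normal."""
        gsb = max_stat_boundaries(2, (1.0,), 0.05)
        reps = 2_000_000
        z = rng.standard_normal((reps, 3))
        pair = A * z[:, :1] + A * z[:, 1:]
        exceed = (pair.max(axis=1) >= gsb.wald[0]).mean()
        se = np.sqrt(0.05 * 0.95 / reps)
        assert exceed == pytest.approx(0.05, abs=3 * se)

    def test_two_stage_against_full_mvn_oracle(self):
        """Joint non-crossing probability of the k=4 solution agrees with an
        independent Genz integration of the 8-dimensional normal."""
        gsb = max_stat_boundaries(4, (0.5, 1.0), 0.025)
        cov = np.empty((8, 8))
        t = [0.5, 1.0]
        for j1 in range(2):
            for j2 in range(2):
                blk = np.full((4, 4), 0.5 * t[min(j1, j2)])
                np.fill_diagonal(blk, t[min(j1, j2)])
                cov[j1 * 4:j1 * 4 + 4, j2 * 4:j2 * 4 + 4] = blk
        upper = np.r_[[gsb.wald[0] * np.sqrt(0.5)] * 4, [gsb.wald[1]] * 4]
        p = multivariate_normal.cdf(upper, mean=np.zeros(8), cov=cov,
                                    rng=3, maxpts=4_000_000, abseps=1e-7,
                                    releps=0)
        assert p == pytest.approx(0.975, abs=2e-5)

    def test_two_arm_matches_recursive_integration_oracle(self):
        """k=1 boundaries agree with the classical one-dimensional recursive
        (grid-convolution) computation of group-sequential exit
        probabilities."""
        for fracs in [(0.5, 1.0), (1 / 3, 2 / 3, 1.0)]:
            gsb = max_stat_boundaries(1, fracs, 0.025)
            exits = _armitage_exit_probs(gsb.wald, np.asarray(fracs))
            assert np.allclose(exits, gsb.alpha_spent, atol=5e-5)
            assert abs(exits.sum() - 0.025) < 5e-4

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            max_stat_boundaries(0, (0.5, 1.0), 0.025)
        with pytest.raises(ValueError):
            max_stat_boundaries(2, (0.7, 0.5, 1.0), 0.025)


def _armitage_exit_probs(wald_bounds, fracs):
    """Independent oracle: recursive numerical integration for a single
    Brownian statistic observed at the given information fractions."""
    inc = np.diff(np.r_[0.0, fracs])
    grid = np.linspace(-10, 10, 4001)
    dx = grid[1] - grid[0]
    dens = norm.pdf(grid, scale=np.sqrt(inc[0]))
    exits = []
    for j, f in enumerate(fracs):
        b = wald_bounds[j] * np.sqrt(f)
        idx = int(np.searchsorted(grid, b))
        dens_b = np.interp(b, grid, dens)
        tail = np.trapezoid(dens[idx:], dx=dx) \
            + 0.5 * (dens_b + dens[idx]) * (grid[idx] - b)
        exits.append(tail)
        keep = np.where(grid < b, dens, 0.0)
        if j < len(fracs) - 1:
            sd = np.sqrt(inc[j + 1])
            trans = norm.pdf((grid[:, None] - grid[None, :]) / sd) / sd
            dens = trans @ keep * dx
    return np.array(exits)


class TestExitProbabilities:
    def test_infinite_boundaries_never_cross(self):
        gsb = max_stat_boundaries(2, (0.5, 1.0), 0.025)
        inf_gsb = type(gsb)(wald=(np.inf, np.inf), alpha_spent=gsb.alpha_spent,
                            n_comparisons=2, info_fractions=(0.5, 1.0),
                            alpha=0.025)
        assert max_stat_exit_prob(inf_gsb).sum() == pytest.approx(0.0)

    def test_shifted_mean_matches_monte_carlo(self, rng):
        """Crossing probabilities under drift agree with simulation."""
        gsb = max_stat_boundaries(2, (0.5, 1.0), 0.025)
        shift = np.array([3.0, 3.0])      # delta * sqrt(I_2)
        exits = max_stat_exit_prob(gsb, mean_shift=shift)
        reps = 400_000
        zf = rng.standard_normal((reps, 2))      # common factors per stage
        ze = rng.standard_normal((reps, 2, 2))   # idiosyncratic
        inc = np.sqrt(0.5)
        v = inc * (A * zf[:, :, None] + A * ze) + 0.5 * shift
        w = np.cumsum(v, axis=1)
        first = np.full(reps, -1)
        for j in (0, 1):
            crossed = w[:, j, :].max(axis=1) >= gsb.wald[j] * np.sqrt([0.5, 1.0][j])
            first = np.where((first < 0) & crossed, j, first)
        for j in (0, 1):
            emp = (first == j).mean()
            se = np.sqrt(emp * (1 - emp) / reps)
            assert exits[j] == pytest.approx(emp, abs=3 * se + 1e-4)


class TestTAdjustment:
    def test_limits(self):
        assert t_adjust_boundary(2.0, 4.0, 1e9) == pytest.approx(2.0, abs=1e-5)
        assert t_adjust_boundary(0.0, 4.0, 7) == pytest.approx(0.0, abs=1e-12)

    def test_composition_against_root_finding(self):
        """sqrt(I) * T^{-1}(Phi(b / sqrt(I))) recomputed by inverting the t
        CDF with a root finder (independent of the quantile routine)."""
        from scipy.optimize import brentq
        from scipy.stats import t as t_dist
        info, df, wald = 193.0, 96, 2.4510
        b = wald * np.sqrt(info)
        got = t_adjust_boundary(b, info, df)
        target = norm.cdf(wald)
        root = brentq(lambda x: t_dist.cdf(x, df) - target, -50, 50,
                      xtol=1e-12)
        assert got == pytest.approx(np.sqrt(info) * root, rel=1e-9)

    def test_adjustment_is_conservative_above_median(self):
        # t quantiles exceed normal quantiles above the median
        assert t_adjust_boundary(2.0, 1.0, 10) > 2.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            t_adjust_boundary(1.0, -1.0, 10)
        with pytest.raises(ValueError):
            t_adjust_boundary(1.0, 1.0, 0)
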