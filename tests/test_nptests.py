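"""Unit and oracle tests for the non-parametric battery components."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from carproc.nptests import (
    BatteryConfig,
    TestResult,
    ba_density_test,
    bootstrap_median_ci,
    bootstrap_median_test,
    correlation_screen,
    hettmansperger_norton,
    jonckheere_terpstra,
    kruskal_wallis,
    notch_interval,
    proxy_group_screen,
    pseudoranks,
    run_battery,
    trend_direction,
)


class TestCorrelationScreen:
    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=20)})
        df["y"] = df["x"]
        df["z"] = -df["x"]
        r, p, codes = correlation_screen(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert r.loc["x", "z"] == pytest.approx(-1.0)

    def test_arithmetic_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.1])
        # brute-force covariance sums
        n = 5
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        sxx = np.sum((x - x.mean()) ** 2)
        syy = np.sum((y - y.mean()) ** 2)
        expected = sxy / math.sqrt(sxx * syy)
        r, _, _ = correlation_screen(pd.DataFrame({"x": x, "y": y}))
        assert r.loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_star_codes(self):
        rng = np.random.default_rng(1)
        n = 500
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "strong": x + 0.1 * rng.normal(size=n),
                           "noise": rng.normal(size=n)})
        _, p, codes = correlation_screen(df)
        assert codes.loc["x", "strong"] == "***"
        assert p.loc["x", "strong"] <= 0.001

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="'c'"):
            correlation_screen(df)

    def test_too_few_rows(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [3.0, 4.0]})
        with pytest.raises(ValueError, match="3"):
            correlation_screen(df)


class TestKruskalWallis:
    def test_identical_observations(self):
        res = kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_enumeration_oracle_extreme_configuration(self):
        """For values 1..6 in groups of 2, the observed split (1,2),(3,4),(5,6)
        achieves the maximal H; exactly the 3! group-permuted assignments do,
        so the exact permutation p-value is 6/90."""
        values = np.arange(1.0, 7.0)
        observed = kruskal_wallis([[1, 2], [3, 4], [5, 6]]).statistic

        def h_stat(perm):
            groups = [perm[0:2], perm[2:4], perm[4:6]]
            ranks = rankdata(np.concatenate(groups))
            rg = [ranks[0:2], ranks[2:4], ranks[4:6]]
            n = 6
            return 12 / (n * (n + 1)) * sum(2 * (np.mean(r) ** 2) for r in rg) - 3 * (n + 1)

        stats_all = [h_stat(np.array(p)) for p in itertools.permutations(values)]
        stats_all = np.array(stats_all)
        assert observed == pytest.approx(stats_all.max(), abs=1e-9)
        exact_p = np.mean(stats_all >= observed - 1e-9)
        assert exact_p == pytest.approx(6 * 2 * 2 * 2 / 720, abs=1e-12)  # = 6/90

    def test_huge_shift_significant(self):
        rng = np.random.default_rng(2)
        g1 = rng.normal(0, 1, 60)
        g2 = rng.normal(5, 1, 60)
        g3 = rng.normal(10, 1, 60)
        res = kruskal_wallis([g1, g2, g3])
        assert res.p_value < 1e-6


class TestProxyGroupScreen:
    def test_screen_on_default_cohort(self, default_cohort, group_labels):
        cohort, _ = default_cohort
        screen = proxy_group_screen(cohort, group_labels=group_labels)
        assert len(screen) == 16
        # planted strong pressure trend is detected by both tests
        assert screen.loc["SAP", "anova_p"] < 1e-6
        assert screen.loc["SAP", "kw_p"] < 1e-6

    def test_small_group_rejected(self):
        cohort = pd.DataFrame({"bmi": [20.0, 27.0, 31.0], "HR": [60.0, 70.0, 80.0]})
        with pytest.raises(ValueError, match=">= 2"):
            proxy_group_screen(cohort, proxies=("HR",))


class TestBootstrapMedian:
    def test_constant_sample_degenerate_ci(self):
        ci = bootstrap_median_ci(np.full(20, 3.5), replicates=500, seed=0)
        assert ci.lower == ci.upper == 3.5

    def test_seed_reproducibility(self):
        x = np.random.default_rng(3).normal(size=50)
        a = bootstrap_median_ci(x, replicates=1000, seed=42)
        b = bootstrap_median_ci(x, replicates=1000, seed=42)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_n_too_small(self):
        with pytest.raises(ValueError):
            bootstrap_median_ci(np.arange(5.0))

    def test_same_sample_not_significant(self):
        g = np.random.default_rng(4).normal(size=40)
        res = bootstrap_median_test(g, g, replicates=1000, seed=0)
        assert not res.significant

    def test_large_shift_significant(self):
        rng = np.random.default_rng(5)
        g1 = rng.normal(0, 1, 100)
        g2 = rng.normal(10, 1, 100)
        res = bootstrap_median_test(g1, g2, replicates=1000, seed=0)
        assert res.significant
        assert res.p_value <= 0.001

    def test_test_reproducible(self):
        rng = np.random.default_rng(6)
        g1, g2 = rng.normal(size=30), rng.normal(size=30)
        a = bootstrap_median_test(g1, g2, replicates=500, seed=9)
        b = bootstrap_median_test(g1, g2, replicates=500, seed=9)
        assert a.p_value == b.p_value


class TestBADensity:
    def test_identical_samples(self):
        g = np.random.default_rng(7).normal(size=30)
        comp = ba_density_test(g, g, nboot=99, seed=0)
        assert comp.statistic == pytest.approx(0.0, abs=1e-20)
        assert comp.p_value == 1.0

    def test_densities_integrate_to_one(self):
        rng = np.random.default_rng(8)
        comp = ba_density_test(rng.normal(size=40), rng.normal(1, 1, 40), nboot=50, seed=0)
        for dens in (comp.density_g1, comp.density_g2):
            assert np.trapezoid(dens, comp.grid) == pytest.approx(1.0, abs=1e-3)
        assert (comp.band_lower <= comp.band_upper).all()

    def test_permutation_matches_enumeration_n4(self):
        a = np.array([0.1, 0.5, 0.9, 1.4])
        b = np.array([3.0, 3.3, 3.9, 4.4])
        exact = ba_density_test(a, b, exact=True).p_value
        mc = ba_density_test(a, b, nboot=4000, seed=1, exact=False).p_value
        assert exact == pytest.approx(2 / 70, abs=1e-12)
        assert abs(mc - exact) < 0.02

    def test_degenerate_bandwidth(self):
        with pytest.raises(ValueError, match="bandwidth"):
            ba_density_test(np.full(12, 1.0), np.full(12, 1.0), nboot=10)

    def test_group_too_small(self):
        with pytest.raises(ValueError, match="n >= 4"):
            ba_density_test([1.0, 2.0, 3.0], np.arange(12.0), nboot=10)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=20), rng.normal(size=20)
        p1 = ba_density_test(a, b, nboot=200, seed=5).p_value
        p2 = ba_density_test(a, b, nboot=200, seed=5).p_value
        assert p1 == p2


class TestJonckheereTerpstra:
    def test_two_group_exact_example(self):
        res = jonckheere_terpstra([[1, 2], [3, 4]], "increasing")
        assert res.statistic == 4.0
        assert res.p_value == pytest.approx(1 / 6)

    def test_interleaved_near_null(self):
        groups = [[1, 6, 8], [2, 4, 9], [3, 5, 7]]  # equal group means
        p_inc = jonckheere_terpstra(groups, "increasing").p_value
        p_dec = jonckheere_terpstra(groups, "decreasing").p_value
        assert 0.1 < p_inc < 0.9
        # one-sided p-values in the two directions are complementary up to ties
        assert p_inc + p_dec == pytest.approx(1.0, abs=0.15)

    def test_decreasing_via_reversal(self):
        inc = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]], "increasing")
        dec = jonckheere_terpstra([[5, 6], [3, 4], [1, 2]], "decreasing")
        assert inc.p_value == pytest.approx(dec.p_value)

    def test_exact_vs_normal_at_n12(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            groups = [rng.normal(size=4), rng.normal(size=4), rng.normal(size=4)]
            p_exact = jonckheere_terpstra(groups, exact=True).p_value
            p_norm = jonckheere_terpstra(groups, exact=False).p_value
            assert abs(p_exact - p_norm) < 0.04

    def test_tie_handling(self):
        res = jonckheere_terpstra([[1, 1], [1, 2]], "increasing", exact=True)
        # J = #{x<y} + 0.5 #{x=y} = 2 + 0.5*2 = 3
        assert res.statistic == 3.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([[1, 2], [], [3, 4]])


class TestHettmanspergerNorton:
    def test_pseudoranks_reduce_to_midranks_for_equal_sizes(self):
        rng = np.random.default_rng(11)
        values = np.round(rng.normal(size=12), 1)  # induce some ties
        labels = np.repeat([0, 1, 2], 4)
        psi = pseudoranks(values, labels, 3)
        np.testing.assert_allclose(psi, rankdata(values), atol=1e-12)

    def test_exact_enumeration_matches_monte_carlo(self):
        groups = [[1.0, 2.0, 4.0], [3.0, 5.0], [6.0, 7.0]]
        p_exact = hettmansperger_norton(groups, exact=True).p_value
        p_mc = hettmansperger_norton(groups, n_perm=20000, seed=1).p_value
        assert abs(p_exact - p_mc) < 0.02

    def test_planted_increasing_trend_detected(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(0, 1, 50), rng.normal(0.6, 1, 30), rng.normal(1.2, 1, 20)]
        res = hettmansperger_norton(groups, alternative="increasing", n_perm=2000, seed=2)
        assert res.significant

    def test_asymptotic_close_to_permutation(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(0, 1, 40), rng.normal(0.3, 1, 25), rng.normal(0.5, 1, 20)]
        p_perm = hettmansperger_norton(groups, n_perm=20000, seed=3).p_value
        p_asym = hettmansperger_norton(groups, method="asymptotic").p_value
        assert abs(p_perm - p_asym) < 0.03

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            hettmansperger_norton([[1.0], [2.0, 3.0], [4.0, 5.0]])


class TestNotchInterval:
    def test_printed_formula(self):
        # median 50, IQR 20, n 100 -> 50 +/- 1.58*20/10 = [46.84, 53.16]
        x = np.concatenate([np.linspace(40, 45, 25), np.linspace(45, 55, 50),
                            np.linspace(55, 60, 25)])
        notch = notch_interval(x)
        half = 1.58 * notch.iqr / 10.0
        assert notch.lower == pytest.approx(notch.median - half)
        assert notch.upper == pytest.approx(notch.median + half)

    def test_direct_values(self):
        from carproc.nptests import NotchInterval

        notch = NotchInterval(median=50.0, q1=40.0, q3=60.0, n=100)
        assert notch.lower == pytest.approx(46.84)
        assert notch.upper == pytest.approx(53.16)

    def test_constant_data_zero_width(self):
        notch = notch_interval(np.full(10, 7.0))
        assert notch.lower == notch.median == notch.upper == 7.0

    def test_quartiles_match_sorted_order_oracle(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=11)
        s = np.sort(x)
        # linear interpolation rule at h = (n-1)*q
        q1 = s[2] + 0.5 * (s[3] - s[2])
        q3 = s[7] + 0.5 * (s[8] - s[7])
        notch = notch_interval(x)
        assert notch.q1 == pytest.approx(q1)
        assert notch.q3 == pytest.approx(q3)

    def test_n_too_small(self):
        with pytest.raises(ValueError):
            notch_interval([1.0, 2.0, 3.0, 4.0])


@pytest.fixture(scope="module")
def planted_battery():
    rng = np.random.default_rng(15)
    values = np.concatenate(
        [rng.normal(0, 1, 200), rng.normal(1.5, 1, 120), rng.normal(3.0, 1, 100)]
    )
    labels = np.array(["NW"] * 200 + ["OW"] * 120 + ["OB"] * 100)
    cfg = BatteryConfig(median_replicates=1000, ba_permutations=200,
                        hn_permutations=1000, seed=7)
    return run_battery(values, labels, config=cfg, indicator="planted")


class TestRunBattery:
    def test_battery_size_and_layout(self, planted_battery):
        assert len(planted_battery.results) == 9
        names = [r.test_name for r in planted_battery.results]
        assert names == ["KW", "median", "median", "median", "BA", "BA", "BA", "JT", "HN"]
        pairs = [r.groups_compared for r in planted_battery.results[1:7]]
        assert pairs == ["NW-OW", "NW-OB", "OW-OB"] * 2

    def test_alphas(self, planted_battery):
        for r in planted_battery.ba_tests:
            assert r.alpha == pytest.approx(0.05 / 3)
        for r in [planted_battery.kw, *planted_battery.median_tests,
                  planted_battery.jt, planted_battery.hn]:
            assert r.alpha == 0.05

    def test_strong_planted_shift_all_significant(self, planted_battery):
        assert planted_battery.n_significant == 9

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(16)
        base = rng.normal(size=100)
        values = np.concatenate([base, base, base])
        labels = np.array(["NW"] * 100 + ["OW"] * 100 + ["OB"] * 100)
        cfg = BatteryConfig(median_replicates=500, ba_permutations=100,
                            hn_permutations=500, seed=1)
        battery = run_battery(values, labels, config=cfg)
        assert battery.n_significant == 0

    def test_determinism(self):
        rng = np.random.default_rng(17)
        values = rng.normal(size=120)
        labels = np.array(["NW"] * 50 + ["OW"] * 40 + ["OB"] * 30)
        cfg = BatteryConfig(median_replicates=300, ba_permutations=100,
                            hn_permutations=300, seed=3)
        b1 = run_battery(values, labels, config=cfg)
        b2 = run_battery(values, labels, config=cfg)
        assert [r.p_value for r in b1.results] == [r.p_value for r in b2.results]

    def test_auto_direction(self):
        values = np.concatenate([np.full(30, 1.0), np.full(30, 2.0), np.arange(30) + 3.0])
        labels = np.array(["NW"] * 30 + ["OW"] * 30 + ["OB"] * 30)
        assert trend_direction(values, labels) == "increasing"
        assert trend_direction(-values, labels) == "decreasing"

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="present"):
            run_battery(np.arange(20.0), np.array(["NW"] * 10 + ["OW"] * 10))


class TestResultInvariants:
    def test_significance_consistency_enforced(self):
        with pytest.raises(ValueError):
            TestResult("KW", 1.0, 0.2, 0.05, True)
        with pytest.raises(ValueError):
            TestResult("KW", 1.0, 1.5, 0.05, False)

    def test_monotone_power_in_shift(self):
        """Rejection rate of the KW test is non-decreasing in the planted
        shift (3-point check)."""
        rng = np.random.default_rng(18)
        rates = []
        for shift in (0.0, 0.5, 1.5):
            rej = 0
            for _ in range(60):
                groups = [rng.normal(0, 1, 30), rng.normal(shift / 2, 1, 30),
                          rng.normal(shift, 1, 30)]
                rej += kruskal_wallis(groups).significant
            rates.append(rej / 60)
        assert rates[0] <= rates[1] + 0.05
        assert rates[1] <= rates[2] + 0.05
        assert rates[2] > 0.9
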