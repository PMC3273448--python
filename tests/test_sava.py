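"""Classical variation statistics against hand arithmetic and literal oracles."""

import numpy as np
import pytest
from scipy import stats

from arealvar import (ArealCounts, coefficient_of_variation,
                      empirical_bayes_statistic, extremal_quotient,
                      indirect_utilization_ratio,
                      systematic_component_of_variation, variation_statistics)


def make_counts(o, e, N=None):
    o = np.asarray(o)
    N = np.asarray(N if N is not None else np.maximum(np.asarray(e) * 5, 1.0))
    return ArealCounts([f"a{i}" for i in range(len(o))], o, N, np.asarray(e, float))


class TestIUR:
    def test_identity_when_observed_equals_expected(self):
        r = indirect_utilization_ratio(make_counts([4, 9], [4.0, 9.0]))
        np.testing.assert_allclose(r.iur, 1.0)
        assert np.all(r.ci_low <= r.iur) and np.all(r.iur <= r.ci_high)

    def test_zero_count_closed_form(self):
        # o=0: lower bound 0, upper bound -ln(0.025)/e from the Gamma(1,1) quantile
        r = indirect_utilization_ratio(make_counts([0], [3.0]), level=0.95)
        assert r.iur[0] == 0 and r.ci_low[0] == 0
        np.testing.assert_allclose(r.ci_high[0], -np.log(0.025) / 3.0, rtol=1e-12)

    def test_interval_matches_exact_poisson_test(self):
        # interval excludes 1 exactly when the exact two-sided test at mean e rejects
        for o, e in [(10, 5.0), (8, 6.0), (2, 7.0), (13, 12.0)]:
            r = indirect_utilization_ratio(make_counts([o], [e]), level=0.95)
            excluded = (r.ci_low[0] > 1) or (r.ci_high[0] < 1)
            p_hi = stats.poisson.sf(o - 1, e)   # Pr(X >= o)
            p_lo = stats.poisson.cdf(o, e)      # Pr(X <= o)
            rejects = min(p_hi, p_lo) < 0.025
            assert excluded == rejects, (o, e)

    def test_significance_flags(self):
        r = indirect_utilization_ratio(make_counts([40, 1], [20.0, 10.0]))
        assert r.significant_high[0] and not r.significant_high[1]
        assert r.significant_low[1] and not r.significant_low[0]


class TestExtremalQuotient:
    def test_constant_rates(self):
        assert extremal_quotient([2.0] * 10) == 1.0

    def test_scale_invariance(self):
        rates = np.linspace(1, 3, 25)
        assert np.isclose(extremal_quotient(rates), extremal_quotient(2 * rates))

    def test_linear_interpolation_rule(self):
        rates = np.arange(1.0, 101.0)
        expected = np.percentile(rates, 95) / np.percentile(rates, 5)
        assert np.isclose(extremal_quotient(rates), expected)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            extremal_quotient([1.0, 0.0])


class TestCV:
    def test_constant(self):
        assert coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0

    def test_hand_example(self):
        # rates (1,3): mean 2, sample sd sqrt(2) -> CV = sqrt(2)/2
        assert np.isclose(coefficient_of_variation([1.0, 3.0]), np.sqrt(2) / 2)

    def test_concentrated_weights_shrink_cvw(self):
        rates = np.array([1.0, 3.0])
        w_equal = coefficient_of_variation(rates, [1.0, 1.0])
        w_conc = coefficient_of_variation(rates, [1e9, 1.0])
        assert w_conc < 0.01 * w_equal


class TestSCVandEB:
    def test_scv_hand_example(self):
        # n=2, o=(20,5), e=(10,10): (1/2)(1 + 0.25) - (1/2)(0.2) = 0.525
        assert np.isclose(
            systematic_component_of_variation(make_counts([20, 5], [10.0, 10.0])),
            0.525)

    def test_scv_negative_under_null(self):
        scv = systematic_component_of_variation(make_counts([4, 9], [4.0, 9.0]))
        assert np.isclose(scv, -(1 / 4 + 1 / 9) / 2)

    def test_eb_hand_example(self):
        # rbar=1.25, weighted var 0.5625, correction 0.125 -> 0.4375
        assert np.isclose(
            empirical_bayes_statistic(make_counts([20, 5], [10.0, 10.0])), 0.4375)

    def test_eb_truncated_at_zero_under_null(self):
        assert empirical_bayes_statistic(make_counts([4, 9], [4.0, 9.0])) == 0.0

    def test_eb_monotone_in_true_heterogeneity(self):
        # method-of-moments estimate grows with the simulated log-risk variance
        rng = np.random.default_rng(5)
        n, reps = 60, 300
        e = np.full(n, 50.0)
        means = []
        for sigma in (0.1, 0.4):
            vals = []
            for _ in range(reps):
                rr = rng.lognormal(0, sigma, size=n)
                o = rng.poisson(e * rr)
                vals.append(empirical_bayes_statistic(make_counts(o, e)))
            means.append(np.mean(vals))
        assert means[1] > means[0]

    def test_literal_formula_oracle(self, counts_rng, random_counts):
        # independent transcription of both formulas, 50 random datasets
        for _ in range(50):
            c = random_counts(counts_rng)
            o, e = c.observed.astype(float), np.asarray(c.expected)
            n = len(o)
            scv_lit = sum(((o[i] - e[i]) / e[i]) ** 2 - 1.0 / e[i]
                          for i in range(n)) / n
            rbar = o.sum() / e.sum()
            eb_lit = max(0.0, sum(e[i] * (o[i] / e[i] - rbar) ** 2 for i in range(n))
                         / e.sum() - rbar * n / e.sum())
            assert abs(systematic_component_of_variation(c) - scv_lit) < 1e-12
            assert abs(empirical_bayes_statistic(c) - eb_lit) < 1e-12

    def test_permutation_invariance(self, counts_rng, random_counts):
        c = random_counts(counts_rng)
        perm = counts_rng.permutation(c.n_areas)
        cp = ArealCounts(np.asarray(c.area_ids)[perm], c.observed[perm],
                         c.population[perm], np.asarray(c.expected)[perm])
        for f in (systematic_component_of_variation, empirical_bayes_statistic):
            assert np.isclose(f(c), f(cp), rtol=1e-12)
        assert np.isclose(extremal_quotient(c.rates), extremal_quotient(cp.rates))
        assert np.isclose(coefficient_of_variation(c.rates, c.population),
                          coefficient_of_variation(cp.rates, cp.population))


class TestVariationStatistics:
    def test_deterministic_under_seed(self, counts_rng, random_counts):
        c = random_counts(counts_rng)
        a = variation_statistics(c, n_boot=200, seed=11)
        b = variation_statistics(c, n_boot=200, seed=11)
        assert a.estimates == b.estimates
        assert a.ci_low == b.ci_low and a.ci_high == b.ci_high

    def test_point_estimates_only_without_bootstrap(self, counts_rng, random_counts):
        vs = variation_statistics(random_counts(counts_rng), n_boot=0)
        assert vs.ci_low is None and vs.ci_high is None
        assert set(vs.estimates) == {"eq", "cv", "cvw", "scv", "eb"}

    def test_constant_risk_data(self):
        n = 30
        e = np.full(n, 200.0)
        c = ArealCounts([f"a{i}" for i in range(n)], e.astype(int), e * 5, e)
        vs = variation_statistics(c, n_boot=300, seed=3)
        assert vs.ci_low["eq"] <= 1.0 + 1e-9 <= vs.ci_high["eq"] * (1 + 1e-9)
        assert abs(vs.estimates["cv"]) < 1e-12
        assert vs.ci_high["cv"] < 0.15
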