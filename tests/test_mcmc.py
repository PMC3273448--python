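"""Core MCMC primitives: ICAR forms, conjugate updates, diagnostics, DIC."""

import numpy as np
import pytest
from scipy import integrate, stats

from arealvar import AdjacencyStructure, MCMCConfig, dic, grid_adjacency, rhat
from arealvar.mcmc import (center_sum_to_zero, gibbs_update_precision,
                           icar_effective_rank, icar_full_conditional,
                           icar_log_density, icar_quadratic_form,
                           mh_update_site, poisson_deviance)


class TestICARQuadraticForm:
    def test_constant_field_is_zero(self, grid3x3):
        assert icar_quadratic_form(np.full(9, 3.7), grid3x3) == 0.0

    def test_path_graph_hand_example(self, path3):
        assert icar_quadratic_form([0.0, 1.0, 3.0], path3) == 5.0

    def test_translation_invariance(self, grid3x3, counts_rng):
        u = counts_rng.standard_normal(9)
        q0 = icar_quadratic_form(u, grid3x3)
        q1 = icar_quadratic_form(u + 11.3, grid3x3)
        assert np.isclose(q0, q1, rtol=1e-10)

    def test_isolated_area_exchangeable_fallback(self):
        adj = AdjacencyStructure.from_edges("ABC", [("A", "B")])
        # C isolated: contributes its square
        assert icar_quadratic_form([1.0, 1.0, 2.0], adj) == 4.0
        assert icar_effective_rank(adj) == 2  # (3 - 2 components) + 1 isolate

    def test_misaligned_field_rejected(self, path3):
        with pytest.raises(ValueError):
            icar_quadratic_form([1.0, 2.0], path3)


class TestICARFullConditional:
    def test_equal_neighbors(self, path3):
        mean, prec = icar_full_conditional([5.0, 0.0, 5.0], 1, path3, tau=2.0)
        assert mean == 5.0 and prec == 4.0

    def test_hand_example(self, path3):
        mean, prec = icar_full_conditional([2.0, 0.0, 4.0], 1, path3, tau=1.0)
        assert mean == 3.0 and prec == 2.0

    def test_precision_linear_in_tau(self, path3):
        _, p1 = icar_full_conditional([0.0, 0.0, 1.0], 0, path3, tau=1.0)
        _, p2 = icar_full_conditional([0.0, 0.0, 1.0], 0, path3, tau=2.0)
        assert p2 == 2 * p1

    def test_isolated_area_falls_back_to_exchangeable(self):
        adj = AdjacencyStructure.from_edges("AB", [])
        mean, prec = icar_full_conditional([3.0, -1.0], 0, adj, tau=4.0)
        assert mean == 0.0 and prec == 4.0


class TestICARLogDensityOracle:
    def test_matches_constrained_mvn_on_4_node_graph(self):
        """ICAR log density via Q-form equals the degenerate-normal density on
        the sum-to-zero subspace (Laplacian eigenbasis), up to one constant."""
        adj = AdjacencyStructure.from_edges(
            "ABCD", [("A", "B"), ("B", "C"), ("C", "D"), ("A", "C")])
        L = adj.laplacian()
        evals, evecs = np.linalg.eigh(L)
        pos = evals > 1e-10

        def oracle(u, tau):
            z = evecs[:, pos].T @ u  # coordinates in the sum-to-zero basis
            var = 1.0 / (tau * evals[pos])
            return float(np.sum(stats.norm.logpdf(z, scale=np.sqrt(var))))

        rng = np.random.default_rng(0)
        pts = [(rng.standard_normal(4), tau) for tau in (0.5, 1.0, 7.3)
               for _ in range(3)]
        pts = [(u - u.mean(), tau) for u, tau in pts]
        offsets = [icar_log_density(u, adj, tau) - oracle(u, tau) for u, tau in pts]
        assert np.max(offsets) - np.min(offsets) < 1e-8


class TestGibbsPrecision:
    def test_no_data_draws_from_prior(self):
        rng = np.random.default_rng(1)
        draws = [gibbs_update_precision(rng, 0.0, 0.0, 2.0, 3.0) for _ in range(4000)]
        # Gamma(2, 3): mean 2/3
        assert np.isclose(np.mean(draws), 2 / 3, rtol=0.05)

    def test_concentrates_on_inverse_variance(self):
        rng = np.random.default_rng(2)
        v = 0.25
        n_eff = 1e6
        draws = [gibbs_update_precision(rng, n_eff * v, n_eff) for _ in range(50)]
        assert np.isclose(np.mean(draws), 1 / v, rtol=0.01)

    def test_rng_contract(self):
        a = gibbs_update_precision(np.random.default_rng(7), 3.0, 10)
        b = gibbs_update_precision(np.random.default_rng(7), 3.0, 10)
        c = gibbs_update_precision(np.random.default_rng(8), 3.0, 10)
        assert a == b and a != c


class TestMHUpdate:
    def test_zero_proposal_sd_never_moves(self):
        rng = np.random.default_rng(0)
        x, acc = mh_update_site(1.5, lambda t: -t * t, 0.0, rng)
        assert x == 1.5

    def test_flat_target_always_accepts(self):
        rng = np.random.default_rng(0)
        accs = [mh_update_site(0.0, lambda t: 0.0, 1.0, rng)[1] for _ in range(200)]
        assert all(accs)

    def test_poisson_lognormal_target_matches_quadrature(self):
        """MH on theta with o ~ Poisson(e*exp(theta)), theta ~ N(0,1):
        chain mean within 3 Monte-Carlo s.e. of the quadrature posterior mean."""
        o, e = 14.0, 10.0

        def log_target(t):
            return o * t - e * np.exp(t) - 0.5 * t * t

        grid = np.linspace(-4, 4, 4001)
        w = np.exp(log_target(grid) - np.max(log_target(grid)))
        mean_q = integrate.simpson(grid * w, x=grid) / integrate.simpson(w, x=grid)

        rng = np.random.default_rng(3)
        x, draws = 0.0, []
        for i in range(22000):
            x, _ = mh_update_site(x, log_target, 0.7, rng)
            if i >= 2000:
                draws.append(x)
        draws = np.asarray(draws)
        batches = draws.reshape(40, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(len(batches))
        assert abs(draws.mean() - mean_q) < 3 * se


class TestCentering:
    def test_already_centered_unchanged(self, grid3x3, counts_rng):
        u = counts_rng.standard_normal(9)
        u -= u.mean()
        c, consts = center_sum_to_zero(u, grid3x3)
        np.testing.assert_allclose(c, u, atol=1e-15)
        np.testing.assert_allclose(consts, [0.0], atol=1e-15)

    def test_constant_absorbed(self, grid3x3):
        c, consts = center_sum_to_zero(np.full(9, 2.5), grid3x3)
        np.testing.assert_allclose(c, 0.0)
        np.testing.assert_allclose(consts, [2.5])

    def test_two_components_centered_separately(self):
        adj = AdjacencyStructure.from_edges("ABCD", [("A", "B"), ("C", "D")])
        c, consts = center_sum_to_zero([1.0, 3.0, 10.0, 20.0], adj)
        np.testing.assert_allclose(c, [-1.0, 1.0, -5.0, 5.0])
        np.testing.assert_allclose(sorted(consts), [2.0, 15.0])


class TestRhat:
    def test_near_one_for_iid_chains(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((2, 1000))
        assert rhat(chains) < 1.05

    def test_large_for_disjoint_chains(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert rhat(chains) > 3.0

    def test_identical_constant_chains(self):
        assert rhat(np.ones((2, 100))) == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="n_chains"):
            rhat(np.zeros((1, 100)))


class TestDIC:
    def test_degenerate_posterior(self):
        d, pd_ = dic(np.full(50, 123.4), 123.4)
        assert pd_ == 0.0 and np.isclose(d, 123.4)

    def test_conjugate_poisson_oracle(self):
        """One Poisson mean with Gamma posterior: DIC from simulated draws
        matches the closed-form Monte-Carlo value within 3 s.e."""
        rng = np.random.default_rng(4)
        o = np.array([7.0, 12.0, 9.0])
        a, b = 1.0 + o.sum(), 1.0 + 3.0  # Gamma(a, b) posterior for the mean
        n_draws = 4000
        mus = rng.gamma(a, 1 / b, size=n_draws)
        dev_draws = np.array([poisson_deviance(o, np.full(3, m)) for m in mus])
        d_at_mean = poisson_deviance(o, np.full(3, mus.mean()))
        dic_val, pd_ = dic(dev_draws, d_at_mean)
        # oracle: pD for one free parameter should be near 1
        se = dev_draws.std(ddof=1) / np.sqrt(n_draws)
        assert abs(pd_ - 1.0) < max(3 * se, 0.1)
        assert np.isclose(dic_val, dev_draws.mean() + pd_)

    def test_negative_pd_warns(self):
        with pytest.warns(UserWarning, match="negative pD"):
            dic(np.full(10, 5.0), 6.0)


class TestConfig:
    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=0)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)

    def test_long_schedule(self):
        c = MCMCConfig.long_schedule(seed=3)
        assert (c.n_iter, c.burn_in, c.thin) == (100_000, 50_000, 10)
        assert c.n_kept == 10_000
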