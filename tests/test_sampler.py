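"""Gibbs sampler internals: full conditionals, reductions, determinism."""

import numpy as np
import pytest
from scipy.stats import invgamma, kstest

from spacebf import SVCModelSpec, fit
from spacebf.graph import SpatialGraph, build_eps_graph
from spacebf.sampler import FusedHSSampler, PosteriorDraws, PriorConfig
from spacebf.simulate import grid_coords
from spacebf.benchmark import make_graph


def path_graph(n):
    coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return SpatialGraph(coords, edges, kind="mst")


@pytest.fixture
def nb_sampler(rng):
    g = make_graph(grid_coords(20, seed=3), "mst", seed=3)
    spec = SVCModelSpec(y=rng.poisson(2.0, 20), x=rng.normal(size=20),
                        graph=g, family="nb", weak_prior_sd2=0.0)
    s = FusedHSSampler(spec, PriorConfig(), seed=9)
    s.omega = rng.uniform(0.5, 2.0, 20)
    s.lambda2 = rng.uniform(0.5, 2.0, (2, g.n_edges))
    s.tau2 = np.array([0.7, 1.3])
    return s


class TestCoefficientConditional:
    def test_banded_equals_dense_precision(self, nb_sampler):
        s = nb_sampler
        Qd, bd = s._dense_Q_b()
        ab, bb = s._banded_Q_b()
        m, bw = s._m, s._bw
        Qb = np.zeros((m, m))
        for r in range(bw + 1):
            for j in range(m):
                i = j - (bw - r)
                if 0 <= i <= j:
                    Qb[i, j] = ab[r, j]
        Qb = Qb + np.triu(Qb, 1).T
        idx = np.empty(m, dtype=int)
        idx[s._i0] = np.arange(s.n)
        idx[s._i1] = s.n + np.arange(s.n)
        assert np.allclose(Qd[np.ix_(idx, idx)], Qb)
        assert np.allclose(bd[idx], bb)

    def test_zero_predictor_slope_prior_only(self, rng):
        g = path_graph(6)
        spec = SVCModelSpec(y=rng.poisson(1.0, 6), x=np.zeros(6), graph=g,
                            family="nb", weak_prior_sd2=0.0)
        s = FusedHSSampler(spec, PriorConfig(), seed=0)
        Q, b = s._dense_Q_b()
        slope_block = Q[6:, 6:]
        ew = s._edge_weights()[1]
        L = np.zeros((6, 6))
        for (u, v), w in zip(g.edges, ew):
            L[u, u] += w
            L[v, v] += w
            L[u, v] -= w
            L[v, u] -= w
        assert np.allclose(slope_block, L + s._diag_prec() * np.eye(6))
        assert np.allclose(b[6:], 0.0)
        assert np.allclose(Q[:6, 6:], 0.0)  # no likelihood coupling

    def test_single_location_conjugate(self, rng):
        g = SpatialGraph(np.zeros((1, 2)), np.empty((0, 2)), kind="eps")
        spec = SVCModelSpec(y=[3], x=[2.0], graph=g, family="nb",
                            weak_prior_sd2=0.0)
        s = FusedHSSampler(spec, PriorConfig(), seed=1)
        s.omega = np.array([1.5])
        Q, b = s._dense_Q_b()
        w, x = 1.5, 2.0
        expect = np.array([[w, w * x], [w * x, w * x * x]]) \
            + s.prior.ridge * np.eye(2)
        assert np.allclose(Q, expect)

    def test_gaussian_fixed_scales_matches_closed_form(self, rng):
        g = path_graph(12)
        spec = SVCModelSpec(y=rng.normal(size=12), x=rng.normal(size=12),
                            graph=g, family="gaussian", weak_prior_sd2=0.0)
        s = FusedHSSampler(spec, PriorConfig(), seed=4, fix_scales=True,
                           fix_sigma2=True)
        Q, b = s._dense_Q_b()
        mu = np.linalg.solve(Q, b)
        cov = np.linalg.inv(Q)
        m = 8000
        draws = np.empty((m, 24))
        for i in range(m):
            s.draw_coefficients()
            draws[i] = np.concatenate([s.beta0, s.beta1])
        se = np.sqrt(np.diag(cov) / m)
        assert np.all(np.abs(draws.mean(0) - mu) < 4 * se)
        rel = np.linalg.norm(np.cov(draws.T) - cov) / np.linalg.norm(cov)
        assert rel < 0.05


class TestIcarReduction:
    def test_icar_equals_clamped_horseshoe(self, rng):
        g = make_graph(grid_coords(15, seed=5), "mst", seed=5)
        y = rng.poisson(2.0, 15)
        x = rng.normal(size=15)
        conds = []
        for prior in ("icar", "horseshoe"):
            spec = SVCModelSpec(y=y, x=x, graph=g, family="nb",
                                weak_prior_sd2=0.0)
            s = FusedHSSampler(spec, PriorConfig(prior=prior), seed=2)
            s.omega = np.linspace(0.5, 1.5, 15)
            s.tau2 = np.array([0.9, 1.1])
            s.lambda2 = np.ones((2, g.n_edges))  # clamp
            conds.append(s._dense_Q_b())
        assert np.allclose(conds[0][0], conds[1][0])
        assert np.allclose(conds[0][1], conds[1][1])

    def test_icar_never_updates_local_scales(self, rng):
        g = path_graph(8)
        spec = SVCModelSpec(y=rng.poisson(1.0, 8), x=rng.normal(size=8),
                            graph=g, family="nb")
        s = FusedHSSampler(spec, PriorConfig(prior="icar"), seed=3)
        for _ in range(5):
            s.step()
        assert np.all(s.lambda2 == 1.0)


class TestLocalScales:
    def test_zero_delta_is_prior_refresh(self, rng):
        g = path_graph(5)
        spec = SVCModelSpec(y=rng.poisson(1.0, 5), x=rng.normal(size=5),
                            graph=g, family="nb")
        s = FusedHSSampler(spec, PriorConfig(), seed=6)
        s.beta0[:] = 2.0
        s.beta1[:] = -1.0   # constant fields: all deltas zero
        s.nu_lambda[:] = 1.0
        draws = []
        for _ in range(4000):
            s.nu_lambda[:] = 1.0
            s.draw_local_scales()
            draws.append(s.lambda2[0, 0])
        # InvGamma(1, 1/nu) with nu = 1
        assert kstest(draws, invgamma(1.0, scale=1.0).cdf).pvalue > 0.01

    def test_half_cauchy_marginal_prior_refresh(self):
        """A prior-only chain (edge difference resampled from N(0, lambda^2)
        each sweep, tau = sigma = 1) must reproduce the half-Cauchy marginal
        of lambda."""
        g = path_graph(2)
        spec = SVCModelSpec(y=[0, 0], x=np.zeros(2), graph=g, family="nb",
                            weak_prior_sd2=0.0)
        s = FusedHSSampler(spec, PriorConfig(), seed=7)
        rng = np.random.default_rng(70)
        s.tau2[:] = 1.0
        lam = []
        for _ in range(20000):
            s.beta1 = np.array([rng.normal(0.0, np.sqrt(s.lambda2[1, 0])), 0.0])
            s.draw_local_scales()
            lam.append(np.sqrt(s.lambda2[1, 0]))
        lam = np.asarray(lam[200:])
        from scipy.stats import halfcauchy
        assert kstest(lam, halfcauchy().cdf).pvalue > 0.01

    def test_outlier_edge_gets_largest_scale(self, rng):
        g = path_graph(10)
        spec = SVCModelSpec(y=rng.poisson(1.0, 10), x=rng.normal(size=10),
                            graph=g, family="nb")
        s = FusedHSSampler(spec, PriorConfig(), seed=8)
        s.beta1 = np.zeros(10)
        s.beta1[5:] = 50.0  # one huge jump on edge (4, 5)
        med = np.zeros((200, g.n_edges))
        for i in range(200):
            s.draw_local_scales()
            med[i] = s.lambda2[1]
        medians = np.median(med, axis=0)
        assert np.argmax(medians) == 4


class TestGlobalScale:
    def test_l_rank_two_components(self):
        coords = np.array([[0.0, 0], [1, 0], [2, 0], [50, 0], [51, 0], [52, 0]])
        g = build_eps_graph(coords, eps=1.5)
        assert g.n_components == 2
        spec = SVCModelSpec(y=np.zeros(6), x=np.zeros(6), graph=g,
                            family="gaussian", weak_prior_sd2=0.0)
        s = FusedHSSampler(spec, PriorConfig(), seed=9)
        assert s.l_rank == 4

    def test_tau2_gibbs_matches_grid_oracle(self, rng):
        """Fixed-beta chain over (tau2, nu_tau) against the analytically
        marginalised density p(tau2 | beta) on a grid."""
        g = path_graph(5)
        spec = SVCModelSpec(y=rng.normal(size=5), x=rng.normal(size=5),
                            graph=g, family="gaussian", weak_prior_sd2=0.0)
        s = FusedHSSampler(spec, PriorConfig(), seed=10, fix_sigma2=True)
        s.beta1 = np.array([0.0, 0.4, 1.0, 1.2, 0.8])
        s.beta0 = np.zeros(5)
        quad = float(np.sum(np.diff(s.beta1) ** 2))
        chain = []
        for _ in range(30000):
            s.draw_global_scales()
            chain.append(s.tau2[1])
        chain = np.asarray(chain[500:])
        # marginal density: IG kernel x half-Cauchy(tau) prior
        lr = s.l_rank

        def logpdf(t2):
            return (-(lr / 2 + 0.5) * np.log(t2) - quad / (2 * t2)
                    - np.log1p(t2))

        grid = np.exp(np.linspace(np.log(1e-4), np.log(1e3), 4000))
        w = np.exp(logpdf(grid) - logpdf(grid).max()) * grid  # log-spacing
        cdf_grid = np.cumsum(w) / w.sum()
        qs = np.interp([0.1, 0.25, 0.5, 0.75, 0.9], cdf_grid, grid)
        emp = np.quantile(chain, [0.1, 0.25, 0.5, 0.75, 0.9])
        assert np.allclose(emp, qs, rtol=0.1)


class TestSigma2AndDispersion:
    def test_sigma2_zero_residual_distribution(self, rng):
        g = path_graph(6)
        y = np.full(6, 1.3)
        spec = SVCModelSpec(y=y, x=np.zeros(6), graph=g, family="gaussian",
                            weak_prior_sd2=0.0)
        s = FusedHSSampler(spec, PriorConfig(), seed=11)
        s.beta0 = y.copy()      # residuals exactly zero, constant field
        s.beta1 = np.zeros(6)   # constant: both quadratic forms vanish
        draws = []
        for _ in range(6000):
            s.draw_sigma2()
            draws.append(s.sigma2)
        # InvGamma(a0 + n/2 + l_rank, b0), a0 = b0 = 0.01
        dist = invgamma(0.01 + 3.0 + 5.0, scale=0.01)
        assert kstest(draws, dist.cdf).pvalue > 0.01
        assert np.min(draws) > 0

    def test_dispersion_recovery_fixed_fields(self, rng):
        n = 500
        g = make_graph(grid_coords(n, seed=12), "mst", seed=12)
        y = rng.negative_binomial(1.0, 0.5, n)  # r = 1, psi = 0.5 (eta = 0)
        spec = SVCModelSpec(y=y, x=np.zeros(n), graph=g, family="nb")
        s = FusedHSSampler(spec, PriorConfig(), seed=13)
        s._adapt_until = 500
        draws = []
        for i in range(2500):
            s.iteration = i
            s.draw_dispersion()   # beta fixed at zero = truth
            draws.append(s.r)
        assert 0.7 < np.median(draws[500:]) < 1.4

    def test_zero_proposal_sd_rejected(self, rng):
        g = path_graph(4)
        spec = SVCModelSpec(y=rng.poisson(1.0, 4), x=np.zeros(4), graph=g,
                            family="nb")
        with pytest.raises(ValueError, match="proposal"):
            FusedHSSampler(spec, PriorConfig(), seed=0, r_proposal_sd=0.0)


class TestFitInterface:
    def test_seed_determinism_bit_identical(self, rng):
        g = make_graph(grid_coords(15, seed=14), "mst", seed=14)
        spec = SVCModelSpec(y=rng.poisson(1.0, 15), x=rng.normal(size=15),
                            graph=g, family="nb")
        d1 = fit(spec, n_iter=200, burn_in=100, seed=77)
        d2 = fit(spec, n_iter=200, burn_in=100, seed=77)
        assert np.array_equal(d1.beta1, d2.beta1)
        assert np.array_equal(d1.loglik, d2.loglik)
        assert np.array_equal(d1.r, d2.r)

    def test_draw_count_and_thinning(self, rng):
        g = path_graph(8)
        spec = SVCModelSpec(y=rng.poisson(1.0, 8), x=rng.normal(size=8),
                            graph=g, family="nb")
        d = fit(spec, n_iter=300, burn_in=100, thin=4, seed=1)
        assert d.n_draws == 50
        assert d.mean_slope.shape == (50,)
        assert np.allclose(d.mean_slope, d.beta1.mean(axis=1))

    def test_all_zero_outcome_warns_and_enables_weak_prior(self):
        g = path_graph(10)
        spec = SVCModelSpec(y=np.zeros(10), x=np.arange(10.0), graph=g,
                            family="nb")
        with pytest.warns(UserWarning, match="all-zero"):
            s = FusedHSSampler(spec, PriorConfig(), seed=0)
        assert s.weak_sd2 == 10.0

    def test_sparsity_rule_triggers(self, rng):
        g = path_graph(20)
        y = np.zeros(20)
        y[:4] = rng.poisson(3.0, 4)  # 80% zeros
        spec = SVCModelSpec(y=y, x=rng.normal(size=20), graph=g, family="nb")
        s = FusedHSSampler(spec, PriorConfig(), seed=0)
        assert s.weak_sd2 == 10.0

    def test_save_load_roundtrip(self, rng, tmp_path):
        g = path_graph(6)
        spec = SVCModelSpec(y=rng.poisson(1.0, 6), x=rng.normal(size=6),
                            graph=g, family="nb")
        d = fit(spec, n_iter=120, burn_in=60, seed=5)
        d.save(tmp_path / "draws")
        back = PosteriorDraws.load(tmp_path / "draws")
        assert np.array_equal(back.beta1, d.beta1)
        assert back.n_iter == 120

    def test_gaussian_null_slope_near_zero(self, rng):
        """With beta1 = 0 truth the slope posterior concentrates near 0."""
        n = 40
        g = make_graph(grid_coords(n, seed=15), "mst", seed=15)
        y = rng.normal(size=n) + 2.0
        x = rng.normal(size=n)
        spec = SVCModelSpec(y=y, x=x, graph=g, family="gaussian")
        d = fit(spec, n_iter=1500, burn_in=750, seed=3)
        from spacebf import global_test
        res = global_test(d)
        assert res.global_ci[0] < 0 < res.global_ci[1]
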