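"""Exact marginal likelihood, ELBO, PX-VBEM steps and the causal test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize, stats

from mrlink import (
    ModelParameters,
    VariationalState,
    causal_test,
    elbo,
    exact_marginal_loglik,
    fit_mr_ld,
    fit_mr_ldp,
    reduce_expansion,
    vbe_step,
    vbm_step,
)
from tests.conftest import block_identity, block_ld, random_instance, toy_dataset


def _rand_state(rng, p, scale=0.05):
    return VariationalState(
        mu_gamma=rng.normal(0, scale, p),
        v_gamma=rng.uniform(1e-4, 1e-2, p),
        mu_alpha=rng.normal(0, scale / 2, p),
        v_alpha=rng.uniform(1e-4, 1e-2, p),
    )


class TestExactMarginalLoglik:
    def test_collapsed_priors_reduce_to_noise_density(self):
        rng = np.random.default_rng(0)
        data, R = random_instance(rng, p=4, corr=0.4)
        params = ModelParameters(beta0=0.3, sigma2_gamma=0.0, sigma2_alpha=0.0)
        got = exact_marginal_loglik(data, R, params)
        Rm = R.blocks[0][1]
        Sg = np.diag(data.s_gamma)
        SG = np.diag(data.s_Gamma)
        want = stats.multivariate_normal.logpdf(data.gamma_hat, cov=Sg @ Rm @ Sg) \
            + stats.multivariate_normal.logpdf(data.Gamma_hat, cov=SG @ Rm @ SG)
        assert got == pytest.approx(want, abs=1e-9)

    def test_single_snp_against_2d_quadrature(self):
        data = toy_dataset([0.1], [0.02], 0.05, 0.04)
        R = block_identity([1])
        params = ModelParameters(beta0=0.2, sigma2_gamma=0.01, sigma2_alpha=0.001, xi=1.0)

        def integrand(a, g):
            return (
                stats.norm.pdf(0.1, loc=g, scale=0.05)
                * stats.norm.pdf(0.02, loc=0.2 * g + a, scale=0.04)
                * stats.norm.pdf(g, scale=np.sqrt(0.01))
                * stats.norm.pdf(a, scale=np.sqrt(0.001))
            )

        val, err = integrate.dblquad(
            integrand, -1.0, 1.0, lambda g: -0.5, lambda g: 0.5, epsabs=1e-12
        )
        assert err / val < 1e-7  # relative error propagates to the log
        assert exact_marginal_loglik(data, R, params) == pytest.approx(np.log(val), abs=1e-6)

    def test_two_snps_against_gauss_hermite(self):
        """4-D tensor Gauss-Hermite quadrature over (gamma, alpha), an
        independent numerical route through the complete-data likelihood."""
        rho = 0.4
        Rm = np.array([[1.0, rho], [rho, 1.0]])
        data = toy_dataset([0.08, -0.05], [0.03, 0.01], [0.04, 0.05], [0.03, 0.04])
        R = block_ld([Rm])
        b0, sg2, sa2, xi = 0.25, 0.004, 0.002, 1.3
        params = ModelParameters(beta0=b0, sigma2_gamma=sg2, sigma2_alpha=sa2, xi=xi)

        nodes, weights = np.polynomial.hermite.hermgauss(35)
        sd_g, sd_a = np.sqrt(sg2), np.sqrt(sa2)
        g1, g2, a1, a2 = np.meshgrid(nodes, nodes, nodes, nodes, indexing="ij")
        gam = np.stack([g1.ravel(), g2.ravel()]) * np.sqrt(2) * sd_g
        alp = np.stack([a1.ravel(), a2.ravel()]) * np.sqrt(2) * sd_a
        W = (weights[:, None, None, None] * weights[None, :, None, None]
             * weights[None, None, :, None] * weights[None, None, None, :]).ravel()

        Sg = np.diag(data.s_gamma)
        SG = np.diag(data.s_Gamma)
        Ag = Sg @ Rm @ np.linalg.inv(Sg)
        AG = SG @ Rm @ np.linalg.inv(SG)
        cov_g = Sg @ Rm @ Sg
        cov_G = SG @ Rm @ SG

        def gauss2(x, means, cov):
            ic = np.linalg.inv(cov)
            d = x[:, None] - means
            quad = np.einsum("in,ij,jn->n", d, ic, d)
            return np.exp(-0.5 * quad) / (2 * np.pi * np.sqrt(np.linalg.det(cov)))

        like = gauss2(data.gamma_hat, xi * (Ag @ gam), cov_g) \
            * gauss2(data.Gamma_hat, AG @ (b0 * gam + alp), cov_G)
        val = np.sum(W * like) / np.pi**2
        assert exact_marginal_loglik(data, R, params) == pytest.approx(np.log(val), abs=1e-4)

    def test_three_snps_against_monte_carlo(self):
        """Prior Monte Carlo with 1e7 draws; the instance uses small prior
        variances so the likelihood weights are tame and the MC error is
        well below the tolerance."""
        idx = np.arange(3)
        Rm = 0.3 ** np.abs(idx[:, None] - idx[None, :])
        data = toy_dataset([0.05, -0.03, 0.02], [0.02, 0.0, -0.01],
                           [0.1, 0.11, 0.09], [0.1, 0.12, 0.11])
        R = block_ld([Rm])
        b0, sg2, sa2 = 0.2, 0.0002, 0.0001
        params = ModelParameters(beta0=b0, sigma2_gamma=sg2, sigma2_alpha=sa2)

        Sg = np.diag(data.s_gamma)
        SG = np.diag(data.s_Gamma)
        Ag = Sg @ Rm @ np.linalg.inv(Sg)
        AG = SG @ Rm @ np.linalg.inv(SG)
        icov_g = np.linalg.inv(Sg @ Rm @ Sg)
        icov_G = np.linalg.inv(SG @ Rm @ SG)
        logz_g = -0.5 * (3 * np.log(2 * np.pi) + np.linalg.slogdet(Sg @ Rm @ Sg)[1])
        logz_G = -0.5 * (3 * np.log(2 * np.pi) + np.linalg.slogdet(SG @ Rm @ SG)[1])

        rng = np.random.default_rng(2024)
        total, n_draws = 0.0, 0
        for _ in range(10):
            gam = rng.normal(0, np.sqrt(sg2), size=(1_000_000, 3))
            alp = rng.normal(0, np.sqrt(sa2), size=(1_000_000, 3))
            d1 = data.gamma_hat - gam @ Ag.T
            d2 = data.Gamma_hat - (b0 * gam + alp) @ AG.T
            lw = (
                logz_g - 0.5 * np.einsum("ni,ij,nj->n", d1, icov_g, d1)
                + logz_G - 0.5 * np.einsum("ni,ij,nj->n", d2, icov_G, d2)
            )
            total += np.exp(lw).sum()
            n_draws += len(lw)
        assert exact_marginal_loglik(data, R, params) == pytest.approx(
            np.log(total / n_draws), abs=1e-4
        )

    def test_block_additivity(self):
        rng = np.random.default_rng(1)
        data, R = random_instance(rng, p=6, block_sizes=[3, 3], corr=0.5)
        params = ModelParameters(beta0=0.1, sigma2_gamma=0.01, sigma2_alpha=0.002)
        whole = exact_marginal_loglik(data, R, params)
        parts = 0.0
        for (start, stop), mat in R.blocks:
            sub = toy_dataset(
                data.gamma_hat[start:stop], data.Gamma_hat[start:stop],
                data.s_gamma[start:stop], data.s_Gamma[start:stop],
            )
            parts += exact_marginal_loglik(sub, block_ld([mat]), params)
        assert whole == pytest.approx(parts, abs=1e-9)


class TestElbo:
    def test_elbo_below_exact_loglik(self):
        rng = np.random.default_rng(2)
        data, R = random_instance(rng, p=5, corr=0.3)
        params = ModelParameters(beta0=0.2, sigma2_gamma=0.005, sigma2_alpha=0.002)
        ll = exact_marginal_loglik(data, R, params)
        for _ in range(5):
            state = _rand_state(rng, 5)
            assert elbo(data, R, params, state) <= ll + 1e-8

    def test_tight_at_analytic_posterior_without_pleiotropy(self):
        """At R = I the no-pleiotropy posterior factorizes exactly, so the
        mean-field bound touches the marginal likelihood."""
        rng = np.random.default_rng(3)
        p = 4
        data, _ = random_instance(rng, p=p)
        R = block_identity([p])
        b0, sg2 = 0.3, 0.01
        params = ModelParameters(beta0=b0, sigma2_gamma=sg2, sigma2_alpha=0.0)
        prec = 1.0 / data.s_gamma**2 + b0**2 / data.s_Gamma**2 + 1.0 / sg2
        mean = (data.gamma_hat / data.s_gamma**2 + b0 * data.Gamma_hat / data.s_Gamma**2) / prec
        state = VariationalState(
            mu_gamma=mean, v_gamma=1.0 / prec,
            mu_alpha=np.zeros(p), v_alpha=np.zeros(p),
        )
        gap = exact_marginal_loglik(data, R, params) - elbo(data, R, params, state, model="mr-ld")
        assert abs(gap) < 1e-6

    def test_moving_away_from_optimum_decreases_elbo(self):
        rng = np.random.default_rng(4)
        data, R = random_instance(rng, p=5)
        params = ModelParameters(beta0=0.1, sigma2_gamma=0.01, sigma2_alpha=0.001)
        state = _rand_state(rng, 5)
        for _ in range(50):
            state = vbe_step(data, R, params, state)
        base = elbo(data, R, params, state)
        worse = state.copy()
        worse.v_gamma = 2.0 * worse.v_gamma
        assert elbo(data, R, params, worse) < base


class TestVbeStep:
    def test_single_snp_variance_closed_form(self):
        data = toy_dataset([0.1], [0.05], 0.03, 0.02)
        R = block_identity([1])
        params = ModelParameters(beta0=0.4, sigma2_gamma=0.01, sigma2_alpha=0.002)
        state = _rand_state(np.random.default_rng(5), 1)
        for _ in range(200):  # to the joint fixed point of (gamma, alpha)
            state = vbe_step(data, R, params, state)
        want = 1.0 / (1 / 0.03**2 + 0.4**2 / 0.02**2 + 1 / 0.01)
        assert state.v_gamma[0] == pytest.approx(want, rel=1e-12)
        # and the mean maximizes the ELBO along this coordinate
        def neg(mu):
            s = state.copy()
            s.mu_gamma = np.array([mu])
            return -elbo(data, R, params, s)
        opt = optimize.minimize_scalar(neg, bounds=(-1, 1), method="bounded",
                                       options=dict(xatol=1e-10))
        assert state.mu_gamma[0] == pytest.approx(opt.x, abs=1e-6)

    def test_sweep_never_decreases_elbo(self):
        rng = np.random.default_rng(6)
        for trial in range(5):
            data, R = random_instance(rng, p=6, block_sizes=[3, 3], corr=0.5)
            params = ModelParameters(beta0=rng.normal(), sigma2_gamma=0.01,
                                     sigma2_alpha=0.003, xi=rng.uniform(0.5, 1.5))
            state = _rand_state(rng, 6)
            before = elbo(data, R, params, state)
            state = vbe_step(data, R, params, state)
            after = elbo(data, R, params, state)
            assert after >= before - 1e-9

    def test_fixed_point_is_stationary(self):
        rng = np.random.default_rng(7)
        data, R = random_instance(rng, p=5, corr=0.4)
        params = ModelParameters(beta0=0.2, sigma2_gamma=0.01, sigma2_alpha=0.002)
        state = _rand_state(rng, 5)
        for _ in range(300):
            state = vbe_step(data, R, params, state)
        again = vbe_step(data, R, params, state)
        assert np.max(np.abs(again.mu_gamma - state.mu_gamma)) < 1e-10
        assert np.max(np.abs(again.mu_alpha - state.mu_alpha)) < 1e-10


class TestVbmStep:
    def test_variance_formula(self):
        rng = np.random.default_rng(8)
        data, R = random_instance(rng, p=4)
        c = 0.0123
        state = VariationalState(
            mu_gamma=np.zeros(4), v_gamma=np.full(4, c),
            mu_alpha=np.zeros(4), v_alpha=np.full(4, c),
        )
        params = vbm_step(data, R, state)
        assert params.sigma2_gamma == pytest.approx(c)
        assert params.sigma2_alpha == pytest.approx(c)

    def test_each_update_maximizes_elbo_coordinatewise(self):
        rng = np.random.default_rng(9)
        data, R = random_instance(rng, p=5, corr=0.3)
        state = _rand_state(rng, 5)
        new = vbm_step(data, R, state)

        def neg_elbo(**kw):
            base = dict(beta0=new.beta0, sigma2_gamma=new.sigma2_gamma,
                        sigma2_alpha=new.sigma2_alpha, xi=new.xi)
            base.update(kw)
            return -elbo(data, R, ModelParameters(**base), state)

        for name, lo, hi in [("beta0", -2, 2), ("xi", 0.01, 3),
                             ("sigma2_gamma", 1e-6, 1), ("sigma2_alpha", 1e-6, 1)]:
            opt = optimize.minimize_scalar(
                lambda v: neg_elbo(**{name: v}), bounds=(lo, hi), method="bounded",
                options=dict(xatol=1e-12),
            )
            assert getattr(new, name) == pytest.approx(opt.x, rel=1e-4, abs=1e-6), name

    def test_em_cycle_monotone(self):
        rng = np.random.default_rng(10)
        data, R = random_instance(rng, p=6, block_sizes=[3, 3])
        params = ModelParameters(beta0=0.0, sigma2_gamma=0.01, sigma2_alpha=1e-4)
        state = _rand_state(rng, 6)
        prev = -np.inf
        for _ in range(10):
            state = vbe_step(data, R, params, state)
            mid = elbo(data, R, params, state)
            assert mid >= prev - 1e-9
            params = vbm_step(data, R, state)
            cur = elbo(data, R, params, state)
            assert cur >= mid - 1e-9
            prev = cur


class TestReduceExpansion:
    def test_identity_and_substitution(self):
        p = ModelParameters(beta0=0.4, sigma2_gamma=0.01, sigma2_alpha=0.002, xi=1.0)
        assert reduce_expansion(p) == p
        q = reduce_expansion(ModelParameters(0.4, 0.01, 0.002, xi=2.0))
        assert q.beta0 == pytest.approx(0.2)
        assert q.sigma2_gamma == pytest.approx(0.04)
        assert q.sigma2_alpha == pytest.approx(0.002)
        assert q.xi == 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        beta0=st.floats(-1.0, 1.0),
        sg2=st.floats(1e-4, 0.05),
        sa2=st.floats(0.0, 0.01),
        xi=st.one_of(st.floats(-2.0, -0.1), st.floats(0.1, 2.0)),
    )
    def test_loglik_invariant_under_reduction(self, beta0, sg2, sa2, xi):
        """The expanded and reduced parameterizations describe the same
        observed-data distribution."""
        rng = np.random.default_rng(11)
        data, R = random_instance(rng, p=3, corr=0.4)
        expanded = ModelParameters(beta0=beta0, sigma2_gamma=sg2,
                                   sigma2_alpha=sa2, xi=xi)
        reduced = reduce_expansion(expanded)
        assert exact_marginal_loglik(data, R, expanded) == pytest.approx(
            exact_marginal_loglik(data, R, reduced), abs=1e-8
        )


class TestFits:
    def test_noiseless_proportionality_recovers_beta(self):
        rng = np.random.default_rng(12)
        p = 30
        gamma_hat = rng.normal(0, 0.1, p)
        beta0 = 0.37
        data = toy_dataset(gamma_hat, beta0 * gamma_hat, 1e-4, 1e-4)
        R = block_identity([p])
        for fitter in (fit_mr_ld, fit_mr_ldp):
            res = fitter(data, R)
            assert res.beta_hat == pytest.approx(beta0, abs=1e-3)

    def test_elbo_trace_monotone_and_kl_nonnegative(self, small_sim_dataset):
        data, R, _ = small_sim_dataset
        res = fit_mr_ldp(data, R)
        assert res.converged
        d = np.diff(res.elbo_trace)
        assert np.all(d >= -1e-8)
        assert res.calibrated_loglik >= res.elbo_trace[-1]

    def test_nesting_mr_ld_equals_pinned_mr_ldp(self, small_sim_dataset):
        data, R, _ = small_sim_dataset
        a = fit_mr_ld(data, R)
        b = fit_mr_ldp(data, R, pin_sigma2_alpha=0.0)
        assert abs(a.beta_hat - b.beta_hat) < 1e-8
        assert b.model == "mr-ldp"

    def test_orientation_invariance(self, small_sim_dataset):
        """Recoding the effect allele of any SNP subset (flipping its effect
        signs and its LD rows/columns) leaves the causal estimate alone."""
        data, R, _ = small_sim_dataset
        rng = np.random.default_rng(13)
        flip = rng.random(data.p) < 0.5
        s = np.where(flip, -1.0, 1.0)
        data2 = toy_dataset(
            s * data.gamma_hat, s * data.Gamma_hat, data.s_gamma, data.s_Gamma,
            block_sizes=[stop - start for (start, stop), _ in R.blocks],
        )
        mats = [np.outer(s[a:b], s[a:b]) * m for (a, b), m in R.blocks]
        R2 = block_ld(mats)
        r1 = fit_mr_ldp(data, R)
        r2 = fit_mr_ldp(data2, R2)
        assert r2.beta_hat == pytest.approx(r1.beta_hat, abs=1e-6)
        assert r2.calibrated_loglik == pytest.approx(r1.calibrated_loglik, abs=1e-6)

    def test_mr_ldp_single_snp_refused(self):
        data = toy_dataset([0.1], [0.05], 0.02, 0.02)
        R = block_identity([1])
        with pytest.raises(ValueError, match="unidentified"):
            fit_mr_ldp(data, R)
        fit_mr_ld(data, R)  # MR-LD is fine with one SNP


class TestCausalTest:
    def test_zero_outcome_effects_give_null_result(self):
        rng = np.random.default_rng(14)
        p = 20
        data = toy_dataset(rng.normal(0, 0.1, p), np.zeros(p), 0.02, 0.02)
        R = block_identity([p])
        res = causal_test(data, R)
        assert abs(res.lrt_stat) < 1e-6
        assert res.p_value == pytest.approx(1.0, abs=1e-6)
        assert abs(res.beta_hat) < 1e-6

    def test_p_value_is_chi2_upper_tail(self, small_sim_dataset):
        data, R, _ = small_sim_dataset
        res = causal_test(data, R, keep_fits=True)
        assert res.lrt_stat >= -1e-6
        assert 0.0 <= res.p_value <= 1.0
        assert res.p_value == pytest.approx(stats.chi2.sf(res.lrt_stat, 1), abs=1e-12)
        # reference point of the chi2(1) mapping used for the test
        assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)
        # detection: the simulated effect (0.1) is strong at this scale
        assert res.p_value < 1e-3
        assert res.se_hat > 0 and np.isfinite(res.se_hat)

    def test_wald_interval_reasonable(self, small_sim_dataset):
        data, R, truth = small_sim_dataset
        res = causal_test(data, R)
        # truth within 4 standard errors on a single replicate
        assert abs(res.beta_hat - 0.1) < 4 * res.se_hat
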