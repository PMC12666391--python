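"""Gibbs sampler: conjugate conditionals, fast-vs-direct gamma draws, chain behavior."""

import numpy as np
import pytest

from sketchvcm import (MCMCState, PriorSpec, SimulationConfig, SketchSpec,
                       TensorBasisSpec, assemble_design, compress, run_mcmc,
                       sample_gamma_cholesky, sample_gamma_fast, simulate_dataset)
from sketchvcm.sampler import (sigma2_conditional_params, tau2_conditional_params,
                               update_beta, update_sigma2, update_tau2)

from conftest import make_sketch_output


def dense_gamma_moments(out, beta, sigma2, tau2):
    """Independent dense computation of the gamma conditional mean/covariance."""
    Z = out.Z_phi
    d = np.repeat(np.asarray(tau2, float), out.H)
    A = Z.T @ Z / sigma2 + np.diag(1.0 / d)
    cov = np.linalg.inv(A)
    mean = cov @ Z.T @ (out.y_phi - out.X_phi @ np.atleast_1d(beta)) / sigma2
    return mean, cov


class TestVarianceConditionals:
    def test_sigma2_parameters(self):
        p = PriorSpec(a_sigma=2.0, b_sigma=0.1)
        assert sigma2_conditional_params(p, M=4, resid_ss=2.0) == (4.0, 1.1)

    def test_sigma2_zero_residual(self):
        p = PriorSpec(a_sigma=2.0, b_sigma=0.1)
        assert sigma2_conditional_params(p, M=10, resid_ss=0.0) == (7.0, 0.1)

    def test_tau2_parameters(self):
        p = PriorSpec(a_tau=2.0, b_tau=0.1)
        assert tau2_conditional_params(p, H=225, gamma_ss=10.0) == (114.5, 5.1)

    def test_sigma2_draw_moments(self, rng):
        """Long-run draws with frozen residual match inverse-gamma mean."""
        out = make_sketch_output(M=8, H=4, n_varying=2, seed=1)
        priors = PriorSpec(a_sigma=4.0, b_sigma=2.0)
        st = MCMCState(beta=np.zeros(1), gamma=np.zeros(8), sigma2=1.0, tau2=[1.0, 1.0])
        draws = np.array([update_sigma2(st, out, priors, rng) for _ in range(20_000)])
        shape, scale = sigma2_conditional_params(priors, out.M, float(out.y_phi @ out.y_phi))
        mean = scale / (shape - 1)
        sd = mean / np.sqrt(shape - 2)
        assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(len(draws))

    def test_tau2_draw_moments(self, rng):
        out = make_sketch_output(M=8, H=6, n_varying=2, seed=2)
        priors = PriorSpec(a_tau=3.0, b_tau=0.5)
        g = np.random.default_rng(0).standard_normal(12)
        st = MCMCState(beta=np.zeros(1), gamma=g, sigma2=1.0, tau2=[1.0, 1.0])
        draws = np.array([update_tau2(st, out, priors, rng) for _ in range(20_000)])
        for j in range(2):
            gj = g[j * 6:(j + 1) * 6]
            shape, scale = tau2_conditional_params(priors, 6, float(gj @ gj))
            mean = scale / (shape - 1)
            sd = mean / np.sqrt(shape - 2)
            assert abs(draws[:, j].mean() - mean) < 3 * sd / np.sqrt(len(draws))

    def test_fixed_sigma2_respected(self, rng):
        out = make_sketch_output(M=8, H=4, n_varying=1)
        st = MCMCState(beta=np.zeros(1), gamma=np.zeros(4), sigma2=1.0, tau2=[1.0])
        p = PriorSpec(fix_sigma2=0.25)
        assert update_sigma2(st, out, p, rng) == 0.25


class TestBetaConditional:
    def test_no_data_limit_is_prior(self, rng):
        """With X_Phi = 0 the conditional reduces to the N(mu, V) prior."""
        out = make_sketch_output(M=10, H=4, n_varying=1, P=2, seed=3)
        out.X_phi = np.zeros_like(out.X_phi)
        priors = PriorSpec(mu_beta=np.array([1.0, -2.0]), V_beta=np.diag([4.0, 0.25]))
        st = MCMCState(beta=np.zeros(2), gamma=np.zeros(4), sigma2=1.0, tau2=[1.0])
        draws = np.array([update_beta(st, out, priors, rng) for _ in range(20_000)])
        L = len(draws)
        assert np.allclose(draws.mean(0), [1.0, -2.0], atol=3 * np.sqrt(4.0 / L))
        assert abs(draws.var(0)[0] - 4.0) < 3 * 4.0 * np.sqrt(2.0 / L)
        assert abs(draws.var(0)[1] - 0.25) < 3 * 0.25 * np.sqrt(2.0 / L)

    def test_scalar_normal_normal_conjugacy(self, rng):
        """P=1 matches the closed-form normal-normal posterior."""
        out = make_sketch_output(M=30, H=4, n_varying=1, P=1, seed=4)
        st = MCMCState(beta=np.zeros(1), gamma=np.zeros(4), sigma2=0.5, tau2=[1.0])
        priors = PriorSpec()  # N(0, 1) prior
        x, r = out.X_phi[:, 0], out.y_phi - out.Z_phi @ st.gamma
        prec = x @ x / st.sigma2 + 1.0
        mean = (x @ r / st.sigma2) / prec
        draws = np.array([update_beta(st, out, priors, rng)[0] for _ in range(20_000)])
        L = len(draws)
        assert abs(draws.mean() - mean) < 3 * np.sqrt(1.0 / prec / L)
        assert abs(draws.var() - 1.0 / prec) < 3 * (1.0 / prec) * np.sqrt(2.0 / L)

    def test_fix_beta_zero(self, rng):
        out = make_sketch_output(M=10, H=4, n_varying=1, P=3)
        st = MCMCState(beta=np.ones(3), gamma=np.zeros(4), sigma2=1.0, tau2=[1.0])
        assert np.all(update_beta(st, out, PriorSpec(fix_beta_zero=True), rng) == 0.0)


class TestGammaSamplers:
    def _state(self, out, sigma2=0.7, tau2=(0.5, 2.0)):
        return MCMCState(beta=np.full(out.X_phi.shape[1], 0.3),
                         gamma=np.zeros(out.H * out.n_varying),
                         sigma2=sigma2, tau2=list(tau2))

    def test_woodbury_identity(self):
        """(Z'Z/s2 + D^-1)^-1 == D - D Z'(Z D Z'/s2 + I)^-1 Z D / s2 to 1e-8."""
        out = make_sketch_output(M=10, H=16, n_varying=2, seed=5)
        sigma2, tau2 = 0.7, np.array([0.5, 2.0])
        Z = out.Z_phi
        d = np.repeat(tau2, out.H)
        direct = np.linalg.inv(Z.T @ Z / sigma2 + np.diag(1.0 / d))
        D = np.diag(d)
        W = np.linalg.inv(Z @ D @ Z.T / sigma2 + np.eye(out.M))
        wood = D - D @ Z.T @ W @ Z @ D / sigma2
        assert np.max(np.abs(direct - wood)) < 1e-8

    def test_zero_design_returns_prior_draw(self):
        """With Z_Phi = 0 the fast draw is exactly gamma-tilde-1 ~ N(0, Delta)."""
        out = make_sketch_output(M=6, H=4, n_varying=2, seed=6)
        out.Z_phi = np.zeros_like(out.Z_phi)
        st = self._state(out)
        rng1 = np.random.default_rng(11)
        g = sample_gamma_fast(st, out, rng1)
        rng2 = np.random.default_rng(11)
        d = np.repeat([0.5, 2.0], 4)
        expected = np.sqrt(d) * rng2.standard_normal(8)
        assert np.allclose(g, expected, atol=1e-12)

    @pytest.mark.parametrize("sampler", [sample_gamma_fast, sample_gamma_cholesky])
    def test_empirical_moments_match_dense_oracle(self, sampler):
        """10^4 draws reproduce the dense conditional mean and covariance."""
        out = make_sketch_output(M=10, H=16, n_varying=2, seed=7)
        st = self._state(out)
        mean, cov = dense_gamma_moments(out, st.beta, st.sigma2, st.tau2)
        rng = np.random.default_rng(123)
        L = 10_000
        draws = np.stack([sampler(st, out, rng) for _ in range(L)])
        sd = np.sqrt(np.diag(cov))
        assert np.all(np.abs(draws.mean(0) - mean) < 4 * sd / np.sqrt(L))
        emp_cov = np.cov(draws.T)
        se_cov = np.sqrt((np.outer(np.diag(cov), np.diag(cov)) + cov**2) / L)
        # ~10^3 simultaneous entries: expected max |z| ~ 3.3, so 5 SE
        assert np.all(np.abs(emp_cov - cov) < 5 * se_cov + 1e-12)

    def test_fast_and_cholesky_same_distribution(self):
        """Both samplers target the same exact conditional: each empirical mean
        sits within 4 SE of the shared dense-oracle mean."""
        out = make_sketch_output(M=12, H=16, n_varying=2, seed=8)
        st = self._state(out)
        mean, cov = dense_gamma_moments(out, st.beta, st.sigma2, st.tau2)
        L = 10_000
        rf, rc = np.random.default_rng(1), np.random.default_rng(2)
        mf = np.stack([sample_gamma_fast(st, out, rf) for _ in range(L)]).mean(0)
        mc = np.stack([sample_gamma_cholesky(st, out, rc) for _ in range(L)]).mean(0)
        se = np.sqrt(np.diag(cov) / L)
        assert np.all(np.abs(mf - mean) < 4 * se)
        assert np.all(np.abs(mc - mean) < 4 * se)

    def test_flat_prior_limit_matches_least_squares(self):
        """tau2 = inf: the conditional mean is the LS solution on compressed data."""
        out = make_sketch_output(M=40, H=4, n_varying=2, seed=9)
        st = MCMCState(beta=np.zeros(1), gamma=np.zeros(8), sigma2=1.0,
                       tau2=[1.0, 1.0])
        st.tau2 = np.array([np.inf, np.inf])  # bypass positivity check: test hook
        r = out.y_phi - out.X_phi @ st.beta
        ls = np.linalg.lstsq(out.Z_phi, r, rcond=None)[0]
        L = 4000
        rng = np.random.default_rng(3)
        draws = np.stack([sample_gamma_cholesky(st, out, rng) for _ in range(L)])
        cov = np.linalg.inv(out.Z_phi.T @ out.Z_phi)
        se = np.sqrt(np.diag(cov) / L)
        assert np.all(np.abs(draws.mean(0) - ls) < 4 * se)

    def test_two_dimensional_hand_computation(self):
        """H Ptilde = 2, M = 3: conditional mean matches the hand 2x2 solve."""
        from sketchvcm.sketch import SketchOutput

        Z = np.array([[1.0, 0.5], [0.0, 2.0], [1.0, -1.0]])
        y = np.array([1.0, 2.0, 0.5])
        X = np.zeros((3, 1))
        out = SketchOutput(y_phi=y, X_phi=X, Z_phi=Z, spec=None, n_varying=2, H=1)
        sigma2, tau2 = 2.0, [1.0, 4.0]
        # A = Z'Z / 2 + diag(1, 1/4); b = Z'y / 2
        A = np.array([[2.0 / 2 + 1.0, (0.5 - 1.0) / 2],
                      [(0.5 - 1.0) / 2, (0.25 + 4.0 + 1.0) / 2 + 0.25]])
        b = np.array([(1.0 + 0.5) / 2, (0.5 + 4.0 - 0.5) / 2])
        det = A[0, 0] * A[1, 1] - A[0, 1] ** 2
        mean_hand = np.array([A[1, 1] * b[0] - A[0, 1] * b[1],
                              -A[0, 1] * b[0] + A[0, 0] * b[1]]) / det
        st = MCMCState(beta=np.zeros(1), gamma=np.zeros(2), sigma2=sigma2, tau2=tau2)
        rng = np.random.default_rng(0)
        draws = np.stack([sample_gamma_cholesky(st, out, rng) for _ in range(8000)])
        cov = np.linalg.inv(A)
        se = np.sqrt(np.diag(cov) / len(draws))
        assert np.all(np.abs(draws.mean(0) - mean_hand) < 4 * se)


class TestRunMCMC:
    def test_conjugate_gamma_posterior(self):
        """With sigma2, tau2, beta fixed, gamma draws are iid from the exact
        normal posterior: empirical mean within 3.5 SE of the closed form."""
        out = make_sketch_output(M=12, H=4, n_varying=1, seed=10)
        priors = PriorSpec(fix_sigma2=0.5, fix_tau2=1.5, fix_beta_zero=True)
        draws = run_mcmc(out, priors, n_iter=10_500, burn_in=500, seed=0,
                         sampler="cholesky")
        mean, cov = dense_gamma_moments(out, np.zeros(out.X_phi.shape[1]), 0.5, [1.5])
        L = draws.n_retained
        se = np.sqrt(np.diag(cov) / L)
        assert np.all(np.abs(draws.gamma.mean(0) - mean) < 3.5 * se)
        assert np.all(draws.sigma2 == 0.5)
        assert np.all(draws.tau2 == 1.5)

    def test_empty_retained_set(self, tiny_fit_inputs):
        *_, out = tiny_fit_inputs
        draws = run_mcmc(out, n_iter=20, burn_in=20, seed=0)
        assert draws.n_retained == 0

    def test_default_burn_in_is_sixty_percent(self, tiny_fit_inputs):
        *_, out = tiny_fit_inputs
        draws = run_mcmc(out, n_iter=50, seed=0)
        assert draws.burn_in == 30 and draws.n_retained == 20

    def test_reproducible_and_positive(self, tiny_fit_inputs):
        *_, out = tiny_fit_inputs
        a = run_mcmc(out, n_iter=80, burn_in=40, seed=123)
        b = run_mcmc(out, n_iter=80, burn_in=40, seed=123)
        assert np.array_equal(a.gamma, b.gamma)
        assert np.all(a.sigma2 > 0) and np.all(a.tau2 > 0)

    def test_auto_sampler_choice(self, tiny_fit_inputs):
        *_, out = tiny_fit_inputs  # M=25 < H*Ptilde=48 -> fast
        assert run_mcmc(out, n_iter=4, burn_in=2, seed=0).sampler == "fast"

    def test_geweke_successive_conditional(self):
        """Re-simulating data inside the Gibbs loop leaves the prior invariant:
        marginal moments of the parameters match their priors."""
        from sketchvcm.sampler import (sample_gamma_fast, update_beta,
                                       update_sigma2, update_tau2)

        M, H, Pt, P = 5, 2, 2, 1
        out = make_sketch_output(M=M, H=H, n_varying=Pt, P=P, seed=11, scale=0.6)
        priors = PriorSpec(a_sigma=6.0, b_sigma=1.0, a_tau=6.0, b_tau=1.0)
        rng = np.random.default_rng(99)
        st = MCMCState(beta=np.zeros(P), gamma=np.zeros(H * Pt),
                       sigma2=0.2, tau2=[0.2, 0.2])
        n_sweep, keep = 30_000, []
        for s in range(n_sweep):
            st.gamma = sample_gamma_fast(st, out, rng)
            st.beta = update_beta(st, out, priors, rng)
            st.sigma2 = update_sigma2(st, out, priors, rng)
            st.tau2 = update_tau2(st, out, priors, rng)
            # data step: y | parameters
            out.y_phi = (out.X_phi @ st.beta + out.Z_phi @ st.gamma
                         + np.sqrt(st.sigma2) * rng.standard_normal(M))
            if s % 5 == 0:
                keep.append((st.sigma2, st.tau2[0], st.beta[0], st.gamma[0]))
        k = np.array(keep)[200:]
        # priors: sigma2, tau2 ~ IG(6,1) mean 0.2; beta ~ N(0,1); gamma mean 0
        n_eff = len(k) / 4.0  # generous correction for residual autocorrelation
        assert abs(k[:, 0].mean() - 0.2) < 4 * 0.1 / np.sqrt(n_eff)
        assert abs(k[:, 1].mean() - 0.2) < 4 * 0.1 / np.sqrt(n_eff)
        assert abs(k[:, 2].mean()) < 4 * 1.0 / np.sqrt(n_eff)
        assert abs(k[:, 3].mean()) < 4 * np.sqrt(0.25) / np.sqrt(n_eff)
        assert abs(k[:, 2].var() - 1.0) < 4 * np.sqrt(2.0 / n_eff)


def test_surface_mse_decreases_with_sample_size():
    """Posterior-median surfaces improve with N on reference-design data."""
    from sketchvcm.metrics import evaluate_fit
    from sketchvcm.sketch import compress

    mse = {}
    for N in (500, 1000, 2000):
        vals = []
        for seed in range(5):
            data = simulate_dataset(SimulationConfig(n_locations=N, seed=1000 + seed,
                                                     n_holdout=50))
            spec = TensorBasisSpec(n_basis=(10, 10), domain=((0, 1), (0, 1)))
            design = assemble_design(data, spec)
            out = compress(data, design, SketchSpec(M=450 if N > 450 else N,
                                                    N=N, seed=seed))
            draws = run_mcmc(out, n_iter=1000, burn_in=500, seed=seed)
            vals.append(evaluate_fit(draws, data, spec, predict_seed=0)["mse_svc"])
        mse[N] = np.mean(vals)
    assert mse[500] > mse[1000] > mse[2000]
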