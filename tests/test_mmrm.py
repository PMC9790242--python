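import numpy as np
import pytest
from scipy import optimize

from cmimpute import SimulationScenario, build_model_frame, fit_mmrm, simulate_trial
from cmimpute.mmrm import observed_data_loglik, _chol_to_theta, _theta_to_chol
from conftest import make_long_df
from cmimpute import TrialDataset

CELL_MEANS = "0 + arm:C(visit)"


def _balanced_dataset(n_per_arm=12, J=3, seed=0):
    rng = np.random.default_rng(seed)
    mu = np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 0.0]])[:, :J]
    A = rng.standard_normal((J, J))
    cov = A @ A.T + J * np.eye(J)
    Y = np.vstack(
        [rng.multivariate_normal(mu[a], cov, size=n_per_arm) for a in (0, 1)]
    )
    arms = ["control"] * n_per_arm + ["intervention"] * n_per_arm
    return TrialDataset(make_long_df(Y, arms)), Y, np.repeat([0, 1], n_per_arm)


class TestClosedFormOracles:
    def test_ml_cell_means_equals_sample_moments(self):
        """Complete balanced data, saturated cell-means model: the ML fit has a
        closed form -- per-cell sample means and the pooled within-cell
        covariance with divisor n."""
        data, Y, arm = _balanced_dataset()
        frame = build_model_frame(data, formula=CELL_MEANS)
        fit = fit_mmrm(frame, objective="ML")
        pred = frame.X @ fit.beta  # fitted per-subject means
        S_oracle = np.zeros((3, 3))
        for a in (0, 1):
            Ya = Y[arm == a]
            assert np.allclose(pred[arm == a], Ya.mean(axis=0), atol=1e-8)
            R = Ya - Ya.mean(axis=0)
            S_oracle += R.T @ R
        S_oracle /= len(Y)
        assert np.allclose(fit.sigma, S_oracle, atol=1e-7)

    def test_reml_and_ml_beta_agree_on_balanced_data(self):
        data, _, _ = _balanced_dataset()
        frame = build_model_frame(data, formula=CELL_MEANS)
        b_reml = fit_mmrm(frame, objective="REML").beta
        b_ml = fit_mmrm(frame, objective="ML").beta
        assert np.allclose(b_reml, b_ml, atol=1e-7)

    def test_single_visit_collapses_to_linear_regression(self):
        rng = np.random.default_rng(3)
        n = 40
        base = rng.standard_normal(n)
        arm01 = np.repeat([0, 1], n // 2)
        y = 1.0 + 0.5 * arm01 + 0.8 * base + rng.standard_normal(n)
        data = TrialDataset(make_long_df(
            y[:, None], np.where(arm01 == 1, "intervention", "control"), baselines=base))
        frame = build_model_frame(data, formula="arm * C(visit) + baseline")
        fit = fit_mmrm(frame, objective="REML")
        X = frame.X[:, 0, :]
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.beta, beta_ols, atol=1e-8)
        rss = float(((y - X @ beta_ols) ** 2).sum())
        assert fit.sigma[0, 0] == pytest.approx(rss / (n - X.shape[1]), rel=1e-7)


class TestBruteForceOracle:
    def _toy_monotone(self):
        Y = np.array(
            [[1.0, 2.0], [2.0, np.nan], [0.5, 1.0],
             [1.5, 2.5], [2.5, np.nan], [0.0, 0.5]]
        )
        arms = ["control", "control", "control",
                "intervention", "intervention", "intervention"]
        return TrialDataset(make_long_df(Y, arms))

    @pytest.mark.parametrize("objective", ["ML", "REML"])
    def test_agrees_with_generic_optimizer(self, objective):
        """Six subjects, J=2, monotone missingness: the fit must agree with a
        brute-force Nelder-Mead maximisation of the observed-data
        (restricted) log-likelihood over (beta, Sigma)."""
        data = self._toy_monotone()
        frame = build_model_frame(data, formula="arm * C(visit)")
        fit = fit_mmrm(frame, objective=objective)
        p = frame.n_params
        reml = objective == "REML"

        def neg(par):
            L = _theta_to_chol(par[p:], 2)
            try:
                return -observed_data_loglik(par[:p], L @ L.T, frame, reml=reml)
            except np.linalg.LinAlgError:
                return np.inf

        x0 = np.concatenate([fit.beta + 0.3, _chol_to_theta(
            np.linalg.cholesky(fit.sigma + 0.2 * np.eye(2)))])
        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        L = _theta_to_chol(res.x[p:], 2)
        if reml:
            # REML profiles beta out; compare the covariance and the objective
            assert np.allclose(fit.sigma, L @ L.T, atol=1e-5)
        else:
            assert np.allclose(fit.beta, res.x[:p], atol=1e-6)
            assert np.allclose(fit.sigma, L @ L.T, atol=1e-6)
        ll_fit = observed_data_loglik(fit.beta, fit.sigma, frame, reml=reml)
        assert ll_fit >= -res.fun - 1e-8

    def test_local_optimum_in_beta(self):
        data = self._toy_monotone()
        frame = build_model_frame(data, formula="arm * C(visit)")
        fit = fit_mmrm(frame, objective="ML")
        ll0 = observed_data_loglik(fit.beta, fit.sigma, frame)
        for k in range(frame.n_params):
            for delta in (-1e-3, 1e-3):
                b = fit.beta.copy()
                b[k] += delta
                assert observed_data_loglik(b, fit.sigma, frame) <= ll0 + 1e-12


class TestInvariants:
    def test_subject_permutation_invariance(self, medium_trial):
        frame = build_model_frame(medium_trial)
        fit = fit_mmrm(frame)
        rng = np.random.default_rng(5)
        perm = rng.permutation(frame.n_subjects)
        fit_p = fit_mmrm(frame.subset(perm))
        assert np.allclose(fit.beta, fit_p.beta, atol=1e-10)
        assert np.allclose(fit.sigma, fit_p.sigma, atol=1e-10)

    def test_gls_identity_at_optimum(self, medium_trial):
        """beta_hat solves the GLS normal equations at sigma_hat."""
        frame = build_model_frame(medium_trial)
        fit = fit_mmrm(frame)
        A = np.zeros((frame.n_params,) * 2)
        b = np.zeros(frame.n_params)
        for i in range(frame.n_subjects):
            obs = np.flatnonzero(frame.fit_mask[i])
            if not obs.size:
                continue
            W = np.linalg.inv(fit.sigma[np.ix_(obs, obs)])
            Xi = frame.X[i, obs]
            A += Xi.T @ W @ Xi
            b += Xi.T @ W @ frame.Y[i, obs]
        assert np.allclose(A @ fit.beta, b, rtol=1e-8, atol=1e-8)

    def test_sigma_positive_definite(self, medium_trial):
        frame = build_model_frame(medium_trial)
        fit = fit_mmrm(frame)
        assert np.all(np.linalg.eigvalsh(fit.sigma) > 0)
        assert np.allclose(fit.sigma, fit.sigma.T)

    def test_singular_design_raises(self, make_dataset):
        data = make_dataset([[1.0, 2.0], [2.0, 1.0]], ["control", "intervention"])
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            frame = build_model_frame(data, formula="arm * C(visit) + baseline")
            fit_mmrm(frame)  # baseline is constant 0 -> collinear with intercept

    def test_covariance_recovery_on_simulated_data(self):
        """Parameter recovery: with 2000 subjects/arm the estimated Sigma is
        close to the generative random-intercept/slope covariance."""
        sc = SimulationScenario(n_per_arm=2000, hypothesis="null",
                                disc_base_prob=(0.0, 0.0))
        data = simulate_trial(sc, seed=11)
        frame = build_model_frame(data)
        fit = fit_mmrm(frame)
        t = sc.times
        cov_y = np.empty((7, 7))
        for a in range(7):
            for b in range(7):
                cov_y[a, b] = (
                    sc.sd_intercept**2
                    + sc.cor_intercept_slope * sc.sd_intercept * sc.sd_slope * (t[a] + t[b])
                    + sc.sd_slope**2 * t[a] * t[b]
                    + (sc.sd_residual**2 if a == b else 0.0)
                )
        # modelled outcome is change from baseline at follow-ups 1..6
        true = np.empty((6, 6))
        for a in range(6):
            for b in range(6):
                true[a, b] = cov_y[a + 1, b + 1] - cov_y[a + 1, 0] - cov_y[0, b + 1] + cov_y[0, 0]
        # conditioning on baseline via the covariate shrinks the covariance;
        # compare against the baseline-adjusted (conditional) covariance
        c0 = np.array([cov_y[a + 1, 0] - cov_y[0, 0] for a in range(6)])
        cond = true - np.outer(c0, c0) / cov_y[0, 0]
        assert np.max(np.abs(fit.sigma - cond)) < 1.5
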