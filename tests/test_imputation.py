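import numpy as np
import pytest

from cmimpute import (
    build_model_frame,
    conditional_mean,
    fit_mmrm,
    marginal_distribution,
    random_conditional_draws,
)
from cmimpute.imputation import (
    MarginalImputationDistribution,
    _reference_mean,
    complete_frame,
    marginal_means,
)
from conftest import make_long_df
from cmimpute import TrialDataset


class TestReferenceMeans:
    """Hand-evaluated examples of the three reference-based formulas."""

    MU = np.array([1.0, 2.0, 3.0])
    MU_REF = np.array([0.0, 1.0, 1.0])

    @pytest.mark.parametrize(
        "method,expected",
        [
            ("J2R", [1.0, 1.0, 1.0]),
            ("CIR", [1.0, 2.0, 2.0]),
            ("CR", [0.0, 1.0, 1.0]),
        ],
    )
    def test_hand_examples_tilde_t_one(self, method, expected):
        out = _reference_mean(self.MU, self.MU_REF, tv=1, method=method)
        assert np.allclose(out, expected)

    def test_prefix_agrees_with_own_trajectory(self):
        for method in ("J2R", "CIR"):
            out = _reference_mean(self.MU, self.MU_REF, tv=2, method=method)
            assert np.allclose(out[:2], self.MU[:2])

    def test_cir_with_flat_reference_holds_last_value(self):
        flat = np.array([0.7, 0.7, 0.7])
        out = _reference_mean(self.MU, flat, tv=1, method="CIR")
        assert np.allclose(out, [1.0, 1.0, 1.0])

    def test_ice_before_first_followup_reduces_to_reference(self):
        for method in ("J2R", "CIR", "CR"):
            out = _reference_mean(self.MU, self.MU_REF, tv=0, method=method)
            assert np.allclose(out, self.MU_REF)


class TestMarginalDistributions:
    def _fitted(self, arm_effect=True):
        rng = np.random.default_rng(1)
        n, J = 40, 3
        mu = np.array([0.0, 1.0, 2.0])
        Y = mu + rng.standard_normal((n, J))
        if arm_effect:
            Y[n // 2:] += 1.5
        arms = ["control"] * (n // 2) + ["intervention"] * (n // 2)
        ice = [np.nan] * n
        strat = ["MAR"] * n
        for i in (n // 2 + 1, n - 1):
            ice[i] = 1
            strat[i] = "J2R"
            Y[i, 1:] = np.nan  # post-ICE outcomes unobserved
        if not arm_effect:
            # mirror the control outcomes (and missingness) into the
            # intervention arm so the fitted treatment effect is exactly zero
            Y[n // 2:] = Y[: n // 2]
            for i in (n // 2 + 1, n - 1):
                Y[i, 1:] = np.nan
                Y[i - n // 2, 1:] = np.nan
        Y[5, 2] = np.nan
        if not arm_effect:
            Y[n // 2 + 5, 2] = np.nan
        data = TrialDataset(make_long_df(Y, arms, ice_visits=ice, strategies=strat))
        frame = build_model_frame(data, formula="arm * C(visit)")
        return frame, fit_mmrm(frame)

    def test_mar_and_control_mean_is_fitted_trajectory(self):
        frame, fit = self._fitted()
        mu = marginal_means(frame, fit, method="J2R")
        pred = frame.X @ fit.beta
        ctl = frame.arm == 0
        assert np.allclose(mu[ctl], pred[ctl])
        no_ice = (frame.arm == 1) & (frame.ice_visit < 0)
        assert np.allclose(mu[no_ice], pred[no_ice])

    def test_no_arm_effect_makes_all_methods_agree(self):
        frame, fit = self._fitted(arm_effect=False)
        base = marginal_means(frame, fit, method="MAR")
        for m in ("CR", "J2R", "CIR"):
            assert np.allclose(marginal_means(frame, fit, method=m), base, atol=1e-8)

    def test_reference_method_without_ice_errors(self):
        frame, fit = self._fitted()
        frame.ice_visit[:] = -1
        frame.strategy[frame.arm == 1] = "CR"
        with pytest.raises(ValueError, match="requires an ICE visit"):
            marginal_means(frame, fit, method=None)

    def test_marginal_distribution_carries_sigma_hat(self):
        frame, fit = self._fitted()
        d = marginal_distribution(2, frame, fit, method="CIR")
        assert np.allclose(d.sigma_tilde, fit.sigma)
        assert np.all(np.linalg.eigvalsh(d.sigma_tilde) > 0)


class TestConditionalMean:
    def _marg(self, mu, sigma):
        return MarginalImputationDistribution(
            mu_tilde=np.asarray(mu, float), sigma_tilde=np.asarray(sigma, float),
            method="MAR",
        )

    def test_no_missing_is_identity(self):
        marg = self._marg([0.0, 0.0], [[1.0, 0.5], [0.5, 1.0]])
        y = np.array([1.3, -0.2])
        assert np.array_equal(conditional_mean(marg, y), y)

    def test_all_missing_returns_marginal_mean(self):
        marg = self._marg([3.0, -1.0], [[1.0, 0.5], [0.5, 1.0]])
        out = conditional_mean(marg, np.array([np.nan, np.nan]))
        assert np.allclose(out, [3.0, -1.0])

    def test_bivariate_regression_value_and_monte_carlo(self):
        """mu=(0,0), Sigma=[[1,.5],[.5,1]], Y1=2 observed: the conditional
        mean of Y2 is 1.0 exactly, and the mean of many random conditional
        draws matches it within the CLT bound."""
        marg = self._marg([0.0, 0.0], [[1.0, 0.5], [0.5, 1.0]])
        y = np.array([2.0, np.nan])
        out = conditional_mean(marg, y)
        assert out[1] == pytest.approx(1.0, abs=1e-12)
        M = 100_000
        draws = random_conditional_draws(marg, y, M=M, seed=123)
        cond_sd = np.sqrt(1.0 - 0.5**2)
        assert abs(draws[:, 1].mean() - 1.0) < 4 * cond_sd / np.sqrt(M)
        assert np.allclose(draws[:, 0], 2.0)

    def test_diagonal_sigma_ignores_observed(self):
        marg = self._marg([5.0, -5.0, 2.0], np.diag([1.0, 2.0, 3.0]))
        out = conditional_mean(marg, np.array([100.0, np.nan, np.nan]))
        assert np.allclose(out[1:], [-5.0, 2.0])

    def test_imputation_is_idempotent(self):
        marg = self._marg([0.0, 1.0, 2.0],
                          [[2.0, 0.8, 0.3], [0.8, 1.5, 0.6], [0.3, 0.6, 1.0]])
        y = np.array([0.4, np.nan, np.nan])
        once = conditional_mean(marg, y)
        again = conditional_mean(marg, once)
        assert np.array_equal(once, again)

    def test_draws_are_seed_deterministic(self):
        marg = self._marg([0.0, 0.0], [[1.0, 0.5], [0.5, 1.0]])
        y = np.array([2.0, np.nan])
        a = random_conditional_draws(marg, y, M=50, seed=7)
        b = random_conditional_draws(marg, y, M=50, seed=7)
        assert np.array_equal(a, b)

    def test_single_draw_zero_conditional_covariance(self):
        marg = self._marg([4.0, 2.0], np.diag([0.0, 0.0]) + 1e-30 * np.eye(2))
        out = random_conditional_draws(marg, np.array([np.nan, np.nan]), M=1, seed=0)
        assert np.allclose(out[0], [4.0, 2.0])


class TestCompleteFrame:
    def test_observed_entries_bit_identical_and_counts(self, medium_trial):
        frame = build_model_frame(medium_trial)
        fit = fit_mmrm(frame)
        comp = complete_frame(frame, fit, method="J2R")
        obs = frame.obs_mask
        assert np.array_equal(comp.completed[obs], frame.Y[obs])
        assert comp.imputed_mask.sum() == (~obs).sum()
        assert not np.isnan(comp.completed).any()

    def test_pattern_completion_matches_per_subject(self, medium_trial):
        frame = build_model_frame(medium_trial)
        fit = fit_mmrm(frame)
        comp = complete_frame(frame, fit, method="CIR")
        mu = marginal_means(frame, fit, method="CIR")
        for i in range(0, frame.n_subjects, 17):
            marg = MarginalImputationDistribution(mu[i], fit.sigma, "CIR")
            assert np.allclose(comp.completed[i], conditional_mean(marg, frame.Y[i]),
                               atol=1e-12)
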