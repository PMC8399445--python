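import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from epimediate._fit import RankDeficientError, logit, ols
from epimediate.mediation import (
    EffectContrast,
    MediatorFit,
    OutcomeFit,
    PairData,
    bootstrap_ci,
    default_contrast,
    delta_se_log_nie,
    effects,
    fit_mediator,
    fit_outcome,
    mediate_pair,
)

finite = st.floats(min_value=-2.0, max_value=2.0, allow_nan=False)


def _mfit(beta0=0.0, beta1=-0.6, beta2=(), sigma2=0.8, cov=None):
    k = 2 + len(beta2)
    return MediatorFit(beta0, beta1, np.asarray(beta2, dtype=float), sigma2,
                       cov if cov is not None else np.zeros((k, k)), 100)


def _ofit(theta0=-4.0, theta1=0.3, theta2=0.4, theta3=0.2, theta4=(), cov=None):
    k = 4 + len(theta4)
    return OutcomeFit(theta0, theta1, theta2, theta3, np.asarray(theta4, dtype=float),
                      cov if cov is not None else np.zeros((k, k)), 100)


class TestFitEngine:
    """The internal OLS / Newton-logistic engine against statsmodels."""

    def test_ols_matches_statsmodels(self, rng):
        X = np.column_stack([np.ones(200), rng.normal(size=(200, 3))])
        y = X @ np.array([1.0, 0.5, -0.3, 0.0]) + rng.normal(size=200)
        mine = ols(X, y)
        ref = sm.OLS(y, X).fit()
        assert mine.coef == pytest.approx(ref.params, rel=1e-9)
        assert np.sqrt(np.diag(mine.cov)) == pytest.approx(ref.bse, rel=1e-9)
        assert mine.sigma2 == pytest.approx(ref.mse_resid, rel=1e-9)

    def test_logit_matches_statsmodels(self, rng):
        X = np.column_stack([np.ones(500), rng.normal(size=(500, 3))])
        y = rng.binomial(1, 1 / (1 + np.exp(-X @ np.array([-1.0, 0.8, -0.5, 0.2])))).astype(float)
        mine = logit(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert mine.converged and not mine.separated
        assert mine.coef == pytest.approx(ref.params, abs=1e-7)
        assert mine.se == pytest.approx(ref.bse, rel=1e-6)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([np.ones(100), x, 2 * x])
        with pytest.raises(RankDeficientError, match="dup"):
            ols(X, rng.normal(size=100), names=["intercept", "x", "dup"])


class TestModelFits:
    def test_mediator_recovery_on_controls(self, rng):
        n = 5000
        a = rng.normal(size=n)
        m = 0.5 - 0.6 * a + rng.normal(scale=0.9, size=n)
        data = PairData(a, m, np.zeros(n, dtype=int), np.empty((n, 0)))
        fit = fit_mediator(data, controls_only=True)
        assert abs(fit.beta1 - (-0.6)) < 3 * np.sqrt(fit.cov[1, 1])
        assert fit.sigma2 == pytest.approx(0.81, rel=0.1)

    def test_controls_only_equals_prefiltered_cases(self, planted_pair_data):
        _, _, data = planted_pair_data
        fit_a = fit_mediator(data, controls_only=True)
        ctrl = data.case == 0
        data_ctrl = PairData(data.exposure[ctrl], data.mediator[ctrl],
                             data.case[ctrl], data.covariates[ctrl])
        fit_b = fit_mediator(data_ctrl, controls_only=False)
        assert fit_a.beta1 == pytest.approx(fit_b.beta1, rel=1e-12)
        assert fit_a.sigma2 == pytest.approx(fit_b.sigma2, rel=1e-12)

    def test_constant_exposure_is_rank_error(self):
        n = 50
        data = PairData(np.ones(n), np.random.default_rng(0).normal(size=n),
                        np.zeros(n, dtype=int), np.empty((n, 0)))
        with pytest.raises(RankDeficientError):
            fit_mediator(data)

    def test_outcome_interaction_recovery_large_n(self, rng):
        n = 20_000
        a = rng.normal(size=n)
        m = -0.6 * a + rng.normal(size=n)
        lp = -2.0 + 0.3 * a + 0.4 * m + 0.2 * a * m
        y = rng.binomial(1, 1 / (1 + np.exp(-lp)))
        data = PairData(a, m, y, np.empty((n, 0)))
        fit = fit_outcome(data)
        assert abs(fit.theta3 - 0.2) < 3 * np.sqrt(fit.cov[3, 3])

    def test_duplicate_covariate_is_rank_error(self, rng):
        n = 200
        a = rng.normal(size=n)
        m = rng.normal(size=n)
        y = rng.binomial(1, 0.3, size=n)
        C = np.column_stack([a, a])
        with pytest.raises(RankDeficientError):
            fit_outcome(PairData(a, m, y, C, ("c1", "c2")))

    def test_null_outcome_wald_p_uniform(self, rng):
        from scipy import stats
        ps = []
        for _ in range(150):
            n = 400
            a, m = rng.normal(size=n), rng.normal(size=n)
            y = rng.binomial(1, 0.3, size=n)
            fit = fit_outcome(PairData(a, m, y, np.empty((n, 0))))
            z = fit.theta2 / np.sqrt(fit.cov[2, 2])
            ps.append(2 * stats.norm.sf(abs(z)))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestEffects:
    def test_no_exposure_mediator_path_gives_null_nie(self):
        _, log_nie, _ = effects(_mfit(beta1=0.0), _ofit(), EffectContrast(0, 1, ()))
        assert log_nie == 0.0

    def test_null_contrast_gives_null_effects(self):
        nde, nie, te = effects(_mfit(), _ofit(), EffectContrast(1.0, 1.0, ()))
        assert (nde, nie, te) == (0.0, 0.0, 0.0)

    def test_worked_example_closed_form(self):
        # theta2=0.4, theta3=0.2, beta1=-0.6, unit contrast:
        # log NIE = (0.4*-0.6 + 0.2*-0.6*1) * 1 = -0.36, OR ~ 0.698
        _, log_nie, _ = effects(_mfit(), _ofit(), EffectContrast(0, 1, ()))
        assert log_nie == pytest.approx(-0.36, abs=1e-12)
        assert np.exp(log_nie) == pytest.approx(0.6977, abs=1e-4)

    @given(finite, finite, finite, finite, finite,
           st.floats(min_value=0.1, max_value=2.0))
    def test_decomposition_exact_and_no_interaction_reduces_to_product(
        self, b0, b1, t1, t2, a1, s2
    ):
        mfit = _mfit(beta0=b0, beta1=b1, sigma2=s2)
        ofit = _ofit(theta1=t1, theta2=t2, theta3=0.0)
        contrast = EffectContrast(0.0, a1, ())
        nde, nie, te = effects(mfit, ofit, contrast)
        assert te == nde + nie  # exact by construction
        assert nie == pytest.approx(t2 * b1 * a1, rel=1e-12, abs=1e-12)

    def test_fitted_pair_decomposition_machine_precision(self, planted_pair_data):
        _, _, data = planted_pair_data
        mfit, ofit = fit_mediator(data), fit_outcome(data)
        nde, nie, te = effects(mfit, ofit, default_contrast(data))
        assert te == pytest.approx(nde + nie, abs=1e-15)


class TestDeltaMethod:
    def test_zero_covariance_gives_zero_se(self):
        se, _ = delta_se_log_nie(_mfit(), _ofit(), EffectContrast(0, 1, ()))
        assert se == 0.0

    def test_se_matches_numerical_jacobian(self, planted_pair_data):
        _, _, data = planted_pair_data
        mfit, ofit = fit_mediator(data), fit_outcome(data)
        contrast = default_contrast(data)
        se, _ = delta_se_log_nie(mfit, ofit, contrast)

        # numeric gradient of log NIE wrt (beta1, theta2, theta3)
        def log_nie_at(b1, t2, t3):
            m2 = _mfit(beta0=mfit.beta0, beta1=b1, beta2=mfit.beta2, sigma2=mfit.sigma2)
            o2 = OutcomeFit(ofit.theta0, ofit.theta1, t2, t3, ofit.theta4,
                            ofit.cov, ofit.n_used)
            return effects(m2, o2, contrast)[1]

        eps = 1e-6
        base = (mfit.beta1, ofit.theta2, ofit.theta3)
        g = np.empty(3)
        for i in range(3):
            hi = list(base); lo = list(base)
            hi[i] += eps; lo[i] -= eps
            g[i] = (log_nie_at(*hi) - log_nie_at(*lo)) / (2 * eps)
        sigma = np.zeros((3, 3))
        sigma[0, 0] = mfit.cov[1, 1]
        sigma[1:, 1:] = ofit.cov[2:4, 2:4]
        assert se == pytest.approx(float(np.sqrt(g @ sigma @ g)), rel=1e-6)

    def test_se_close_to_bootstrap_sd(self, rng):
        cfg_rng = np.random.default_rng(99)
        n = 2000
        a = cfg_rng.normal(size=n)
        m = -0.6 * a + cfg_rng.normal(scale=0.9, size=n)
        y = cfg_rng.binomial(1, 1 / (1 + np.exp(-(-1.5 + 0.3 * a + 0.4 * m + 0.2 * a * m))))
        data = PairData(a, m, y, np.empty((n, 0)))
        contrast = EffectContrast(0, 1, ())
        se, _ = delta_se_log_nie(fit_mediator(data), fit_outcome(data), contrast)
        _, _, reps, _ = bootstrap_ci(data, contrast, B=2000, seed=4)
        assert se == pytest.approx(np.std(reps, ddof=1), rel=0.15)


class TestBootstrap:
    def test_fixed_seed_reproducible(self, planted_pair_data):
        _, _, data = planted_pair_data
        contrast = default_contrast(data)
        lo1, hi1, reps1, _ = bootstrap_ci(data, contrast, B=200, seed=12)
        lo2, hi2, reps2, _ = bootstrap_ci(data, contrast, B=200, seed=12)
        assert lo1 == lo2 and hi1 == hi2
        assert np.array_equal(reps1, reps2)

    def test_stratification_preserves_case_control_counts(self, planted_pair_data):
        # resampling is within strata, so the controls-only mediator fit
        # always sees exactly the original number of controls
        _, _, data = planted_pair_data
        contrast = default_contrast(data)
        _, _, reps, n_dropped = bootstrap_ci(data, contrast, B=150, seed=3)
        assert len(reps) + n_dropped == 150

    def test_intervals_nest_with_level(self, planted_pair_data):
        # same seed -> same replicate vector, so percentile intervals at
        # increasing confidence levels are nested
        _, _, data = planted_pair_data
        contrast = default_contrast(data)
        lo80, hi80, _, _ = bootstrap_ci(data, contrast, B=200, level=0.80, seed=6)
        lo95, hi95, _, _ = bootstrap_ci(data, contrast, B=200, level=0.95, seed=6)
        assert lo95 <= lo80 <= hi80 <= hi95

    def test_small_b_rejected(self, planted_pair_data):
        _, _, data = planted_pair_data
        with pytest.raises(ValueError, match="B"):
            bootstrap_ci(data, default_contrast(data), B=50)


class TestMediatePair:
    def test_estimate_is_consistent_with_truth(self, planted_pair_data):
        cfg, cohort, data = planted_pair_data
        est = mediate_pair(data, "cg000000", "met0000", B=400, seed=5)
        truth = float(cohort.truth["log_nie"].iloc[0])
        assert abs(est.log_nie - truth) < 3 * est.se_log_nie
        assert est.log_te == pytest.approx(est.log_nde + est.log_nie, abs=1e-15)
        assert est.ci_low <= est.log_nie <= est.ci_high
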