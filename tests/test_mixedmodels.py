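import numpy as np
import pandas as pd
import pytest

from deersem.mixedmodels import FitError, fit_mixed_model

sm_api = pytest.importorskip("statsmodels.api")

# Reference fits for tests/data/lmm_oracle.csv computed with lme4 1.1.x
# (lmer/glmer, ML): an independent implementation of the same likelihoods.
LMER_BETA = (1.49664, 0.4724294)
LMER_RE_VAR = 4.001182
LMER_SIGMA2 = 0.9116914
LMER_LL = -710.5932
GLMER_BETA = (0.4906562, 0.8495341)
GLMER_RE_VAR = 2.27747
GLMER_LL = -258.5027


def test_gaussian_no_re_matches_ols(lmm_oracle_data):
    d = lmm_oracle_data
    fit = fit_mixed_model(d, "y", ["x"], "gaussian", [])
    ols = sm_api.OLS(d["y"], sm_api.add_constant(d["x"])).fit()
    np.testing.assert_allclose(fit.params, ols.params, rtol=1e-8)
    # ML variance: statsmodels loglik for OLS is also the ML loglik
    assert fit.loglik == pytest.approx(float(ols.llf), rel=1e-8)


def test_binomial_no_re_matches_glm(lmm_oracle_data):
    d = lmm_oracle_data
    fit = fit_mixed_model(d, "yb", ["x"], "binomial", [])
    glm = sm_api.GLM(d["yb"], sm_api.add_constant(d["x"]),
                     family=sm_api.families.Binomial()).fit()
    np.testing.assert_allclose(fit.params, np.asarray(glm.params), rtol=1e-6)
    np.testing.assert_allclose(fit.bse, np.asarray(glm.bse), rtol=1e-4)
    assert fit.loglik == pytest.approx(float(glm.llf), rel=1e-8)


def test_gaussian_random_intercept_matches_lmer(lmm_oracle_data):
    fit = fit_mixed_model(lmm_oracle_data, "y", ["x"], "gaussian", ["block"])
    np.testing.assert_allclose(fit.params, LMER_BETA, rtol=1e-5)
    assert fit.re_var["block"] == pytest.approx(LMER_RE_VAR, rel=1e-4)
    assert fit.sigma2 == pytest.approx(LMER_SIGMA2, rel=1e-4)
    assert fit.loglik == pytest.approx(LMER_LL, abs=1e-3)
    assert fit.k == 4  # intercept, slope, RE variance, residual variance


def test_binomial_random_intercept_matches_glmer(lmm_oracle_data):
    fit = fit_mixed_model(lmm_oracle_data, "yb", ["x"], "binomial", ["block"])
    # both sides are Laplace approximations with slightly different
    # profiling conventions; agreement is approximation-level, not exact
    np.testing.assert_allclose(fit.params, GLMER_BETA, atol=0.05)
    assert fit.re_var["block"] == pytest.approx(GLMER_RE_VAR, rel=5e-2)
    assert fit.loglik == pytest.approx(GLMER_LL, abs=0.1)


def test_conditional_r2_at_least_marginal(lmm_oracle_data):
    for resp, fam in [("y", "gaussian"), ("yb", "binomial")]:
        fit = fit_mixed_model(lmm_oracle_data, resp, ["x"], fam, ["block"])
        assert fit.r2_conditional >= fit.r2_marginal - 1e-12
        assert 0.0 <= fit.r2_marginal <= 1.0
        assert 0.0 <= fit.r2_conditional <= 1.0


def test_crossed_random_intercepts_improve_on_nested_subset(lmm_oracle_data):
    one = fit_mixed_model(lmm_oracle_data, "y", ["x"], "gaussian", ["block"])
    two = fit_mixed_model(lmm_oracle_data, "y", ["x"], "gaussian",
                          ["block", "yb"])
    assert two.loglik >= one.loglik - 1e-6  # nested: extra variance can't hurt ML
    assert two.k == one.k + 1


def test_theta_warm_start_reaches_same_optimum(lmm_oracle_data):
    cold = fit_mixed_model(lmm_oracle_data, "y", ["x"], "gaussian",
                           ["block", "yb"])
    warm = fit_mixed_model(lmm_oracle_data, "y", ["x"], "gaussian",
                           ["block", "yb"], theta_start=cold.theta)
    assert warm.loglik == pytest.approx(cold.loglik, abs=1e-6)
    np.testing.assert_allclose(warm.params, cold.params, rtol=1e-5)


def test_min_rows_guard(lmm_oracle_data):
    small = lmm_oracle_data.head(12)
    with pytest.raises(FitError):
        fit_mixed_model(small, "y", ["x"], "gaussian", ["block"],
                        min_rows_per_param=10)


def test_unknown_family_and_missing_column(lmm_oracle_data):
    with pytest.raises(ValueError):
        fit_mixed_model(lmm_oracle_data, "y", ["x"], "poisson", [])
    with pytest.raises(KeyError):
        fit_mixed_model(lmm_oracle_data, "y", ["nope"], "gaussian", [])
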