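import numpy as np
import pandas as pd
import pytest

from deersem.mixedmodels import fit_mixed_model
from deersem.sem import (
    COMPONENT_SPECS,
    ComponentSpec,
    MixedModelComponent,
    fit_component,
    iq_effect,
    residual_correlation,
    select_random_effects,
    standardize_coefficients,
)


def make_data(rng, n=400, block_sd=0.0):
    block = rng.integers(0, 8, size=n)
    x1 = rng.normal(0, 2, n)
    x2 = rng.normal(1, 0.5, n)
    y = 1.0 + 0.8 * x1 - 1.5 * x2 + block_sd * rng.normal(size=8)[block] \
        + rng.normal(0, 1, n)
    eta = 0.5 * x1
    yb = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2, "yb": yb,
                         "block_id": block, "year": rng.integers(2011, 2015, n)})


def test_component_specs_are_coherent():
    assert set(COMPONENT_SPECS) == {"fertility", "body_mass", "roe_density",
                                    "muntjac_density"}
    assert COMPONENT_SPECS["fertility"].family == "binomial"
    assert COMPONENT_SPECS["fertility"].controls == ["week_class"]
    assert COMPONENT_SPECS["body_mass"].controls == ["week"]
    assert COMPONENT_SPECS["roe_density"].correlated_error_partner == "muntjac_density"
    assert COMPONENT_SPECS["muntjac_density"].correlated_error_partner == "roe_density"


def test_fit_component_rejects_unknown_predictor(rng):
    spec = ComponentSpec(name="t", response="y", family="gaussian",
                         candidates=["x1", "x2"])
    with pytest.raises(ValueError):
        fit_component(spec, ["x3"], make_data(rng))


def test_standardize_matches_manual(rng):
    d = make_data(rng)
    fit = fit_mixed_model(d, "y", ["x1", "x2"], "gaussian", [])
    std = standardize_coefficients(fit, d)
    sd_y = d["y"].std(ddof=1)
    for name in ("x1", "x2"):
        want = fit.coef(name) * d[name].std(ddof=1) / sd_y
        assert std[name] == pytest.approx(want)
    assert "Intercept" not in std


def test_standardize_binomial_uses_latent_sd(rng):
    d = make_data(rng)
    fit = fit_mixed_model(d, "yb", ["x1"], "binomial", [])
    std = standardize_coefficients(fit, d)
    want = fit.coef("x1") * d["x1"].std(ddof=1) / fit.latent_sd
    assert std["x1"] == pytest.approx(want)
    assert fit.latent_sd >= np.pi / np.sqrt(3) - 1e-9


def test_iq_effect_gaussian_is_slope_times_iqr(rng):
    d = make_data(rng)
    fit = fit_mixed_model(d, "y", ["x1", "x2"], "gaussian", [])
    q1, q3 = np.percentile(d["x1"], [25, 75])
    assert iq_effect(fit, "x1", d) == pytest.approx(fit.coef("x1") * (q3 - q1))
    with pytest.raises(KeyError):
        iq_effect(fit, "nope", d)


def test_iq_effect_binomial_in_percentage_points(rng):
    d = make_data(rng)
    fit = fit_mixed_model(d, "yb", ["x1"], "binomial", [])
    eff = iq_effect(fit, "x1", d)
    assert -100.0 <= eff <= 100.0
    assert np.sign(eff) == np.sign(fit.coef("x1"))


def test_residual_correlation(rng):
    d = make_data(rng)
    fa = fit_mixed_model(d, "y", ["x1"], "gaussian", [])
    fb = fit_mixed_model(d, "x2", ["x1"], "gaussian", [])
    r = residual_correlation(fa, fb)
    assert -1.0 <= r <= 1.0
    # oracle: plain correlation of the two residual vectors
    assert r == pytest.approx(float(np.corrcoef(fa.resid, fb.resid)[0, 1]))
    fc = fit_mixed_model(d.head(100), "y", ["x1"], "gaussian", [])
    with pytest.raises(ValueError):
        residual_correlation(fa, fc)


def test_select_random_effects_prefers_real_block_structure(rng):
    spec = ComponentSpec(name="t", response="y", family="gaussian",
                         candidates=["x1", "x2"])
    strong = make_data(rng, n=600, block_sd=3.0)
    assert "block_id" in select_random_effects(spec, strong)
    # with no grouping signal the simplest structure must win
    flat = make_data(rng, n=600, block_sd=0.0)
    assert select_random_effects(spec, flat) == ()


def test_mixed_model_component_estimator(rng):
    d = make_data(rng)
    est = MixedModelComponent(response="y", fixed=("x1", "x2"))
    est.fit(d)
    assert est.coef_.shape == (3,)
    assert np.isfinite(est.aicc_)
    pred = est.predict(d)
    assert pred.shape == (len(d),)
    assert np.corrcoef(pred, d["y"])[0, 1] > 0.8
    # sklearn protocol: params round-trip
    assert est.get_params()["response"] == "y"
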