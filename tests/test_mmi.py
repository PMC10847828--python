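import numpy as np
import pandas as pd
import pytest

from deersem.density_surface import DensityRaster
from deersem.mmi import (
    CandidateModel,
    aicc,
    akaike_weights,
    compare_effect_strengths,
    confidence_set,
    enumerate_models,
    model_average,
    propagate,
    resample_density_raster,
)
from deersem.raster import Raster


def test_aicc_closed_form():
    # -2(-12) + 2*3 + 2*3*4/(10-3-1) = 24 + 6 + 4 = 34
    assert aicc(-12.0, 3, 10) == pytest.approx(34.0)
    with pytest.raises(ValueError):
        aicc(-12.0, 3, 4)


def test_akaike_weights_closed_form():
    w = akaike_weights([100.0, 102.0, 104.0])
    np.testing.assert_allclose(w, [0.6652, 0.2447, 0.0900], atol=5e-5)
    assert w.sum() == pytest.approx(1.0)
    # invariant to a constant shift
    np.testing.assert_allclose(w, akaike_weights([0.0, 2.0, 4.0]))


def test_enumerate_models():
    combos = enumerate_models(["a", "b"], [400.0, 500.0])
    assert len(combos) == 8  # 2^2 subsets x 2 radii
    assert (("a", "b"), 400.0) in combos and ((), 500.0) in combos
    with pytest.raises(ValueError):
        enumerate_models([f"x{i}" for i in range(13)], [400.0])


def _toy_models(weights):
    out = []
    for i, w in enumerate(weights):
        m = CandidateModel(component="t", subset=("a",) if i % 2 else (),
                           radius_m=400.0 + 50.0 * i, loglik=0.0, k=1, n=50,
                           coefs={"a": 1.0}, ses={"a": 0.1}, aicc=0.0)
        m.weight = w
        out.append(m)
    return out


def test_confidence_set_is_minimal_prefix():
    ms = _toy_models([0.5, 0.3, 0.15, 0.05])
    cs = confidence_set(ms, 0.85)
    assert [m.weight for m in cs] == [0.5, 0.3, 0.15]
    assert sum(m.weight for m in confidence_set(ms, 0.79)) >= 0.79
    assert len(confidence_set(ms, 0.5)) == 1
    with pytest.raises(ValueError):
        confidence_set(ms, 1.5)


def test_model_average_full_vs_natural_closed_form():
    # two models, equal AICc -> weights 0.5/0.5; "a" only in the second
    m1 = CandidateModel("t", (), 400.0, loglik=-10.0, k=2, n=50,
                        coefs={}, ses={}, aicc=24.0)
    m2 = CandidateModel("t", ("a",), 400.0, loglik=-10.0, k=3, n=50,
                        coefs={"a": 2.0}, ses={"a": 0.4}, aicc=24.0)
    full = model_average([m1, m2], ["a"], method="full").table
    nat = model_average([m1, m2], ["a"], method="natural").table
    assert full.loc["a", "estimate"] == pytest.approx(1.0)   # 0.5*0 + 0.5*2
    assert nat.loc["a", "estimate"] == pytest.approx(2.0)    # renormalised
    assert full.loc["a", "importance"] == pytest.approx(0.5)
    # unconditional SE: 0.5*sqrt(0+1) + 0.5*sqrt(0.16+1)
    want = 0.5 * 1.0 + 0.5 * np.sqrt(0.16 + 1.0)
    assert full.loc["a", "se"] == pytest.approx(want)
    assert full.loc["a", "ci_lo"] == pytest.approx(1.0 - 1.96 * want)
    # every table carries the natural effect-size columns, whichever method
    # fills the headline columns
    assert full.loc["a", "natural_estimate"] == pytest.approx(2.0)
    assert full.loc["a", "natural_estimate"] == nat.loc["a", "estimate"]
    assert full.loc["a", "natural_ci_lo"] == pytest.approx(nat.loc["a", "ci_lo"])
    assert nat.loc["a", "natural_ci_hi"] == nat.loc["a", "ci_hi"]
    with pytest.raises(ValueError):
        model_average([m1, m2], ["a"], method="bayes")


def test_model_average_weighted_radius():
    m1 = CandidateModel("t", (), 400.0, -10.0, 2, 50, {}, {}, aicc=24.0)
    m2 = CandidateModel("t", (), 600.0, -10.0, 2, 50, {}, {}, aicc=24.0)
    avg = model_average([m1, m2], ["a"])
    assert avg.weighted_mean_radius == pytest.approx(500.0)
    assert avg.weighted_radius_sd == pytest.approx(100.0)


def _density_raster(vals, cv):
    g = Raster(np.asarray(vals, dtype=float), cellsize=100.0)
    return DensityRaster(species="roe", year=2011, density=g,
                         cv=g.copy_with(np.full_like(g.values, cv)))


def test_resample_cv_zero_is_identity():
    dr = _density_raster([[1.0, 2.0], [3.0, 4.0]], 0.0)
    out = resample_density_raster(dr, 0)
    np.testing.assert_array_equal(out.density.values, dr.density.values)


def test_resample_is_mean_preserving(rng):
    dr = _density_raster(np.full((50, 50), 8.0), 0.3)
    draws = np.stack([resample_density_raster(dr, rng).density.values
                      for _ in range(40)])
    assert draws.mean() == pytest.approx(8.0, rel=0.01)
    cv_hat = draws.std() / draws.mean()
    assert cv_hat == pytest.approx(0.3, rel=0.05)
    assert np.all(draws > 0)


def test_welch_closed_form():
    t, df, p = compare_effect_strengths([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    assert t == pytest.approx(-1.2247, abs=1e-4)
    assert df == pytest.approx(4.0, abs=1e-9)
    assert 0.0 < p < 1.0


def _const_pipeline(seed):
    tbl = pd.DataFrame({"predictor": ["a"], "estimate": [1.0], "se": [0.1],
                        "ci_lo": [0.8], "ci_hi": [1.2], "importance": [0.9],
                        "in_set": [True], "std_estimate": [0.5],
                        "natural_estimate": [1.1], "natural_se": [0.1],
                        "natural_ci_lo": [0.9],
                        "natural_ci_hi": [1.3]}).set_index("predictor")
    from deersem.mmi import ComponentAverage
    return {"t": ComponentAverage("t", tbl, 500.0, 0.0, 1, 10.0)}


def test_propagate_deterministic_and_averages():
    r1 = propagate(_const_pipeline, n_iter=5, seed=42)
    r2 = propagate(_const_pipeline, n_iter=5, seed=42)
    pd.testing.assert_frame_equal(r1.components["t"], r2.components["t"])
    assert r1.components["t"].loc["a", "estimate"] == pytest.approx(1.0)
    assert r1.weighted_mean_radius == pytest.approx(500.0)
    assert bool(r1.supported("t").loc["a"])
    assert r1.n_failed == 0


def test_propagate_aborts_on_too_many_failures():
    def bad(seed):
        raise RuntimeError("boom")
    with pytest.raises(RuntimeError):
        propagate(bad, n_iter=5, seed=0, max_failure_frac=0.2)
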