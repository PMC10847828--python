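import numpy as np
import pandas as pd
import pytest

from deersem.density_surface import (
    DensityRaster,
    DensitySmoother,
    HalfNormalDetectionFunction,
    fit_detection,
    fit_spatial_model,
    moving_average_raster,
    predict_density_raster,
    segment_abundance,
)
from deersem.raster import Raster


def halfnormal_distances(rng, sigma, n, w):
    """Sample perpendicular distances from the truncated half-normal."""
    out = []
    while len(out) < n:
        d = np.abs(rng.normal(0.0, sigma, size=2 * n))
        out.extend(d[d <= w].tolist())
    return np.array(out[:n])


def obs_frame(distances, group_size=1.0, visibility="open"):
    n = len(distances)
    return pd.DataFrame({
        "perpendicular_distance": distances,
        "group_size": np.full(n, group_size),
        "visibility_class": [visibility] * n,
        "segment_id": np.arange(n) % 50,
    })


def test_halfnormal_shape_identities():
    m = HalfNormalDetectionFunction(truncation_m=150.0)
    m.coef_ = np.array([np.log(25.0)])
    m.coef_names_ = ["log_sigma_0"]
    assert m.detection_probability(0.0) == pytest.approx(1.0)
    assert m.detection_probability(25.0) == pytest.approx(np.exp(-0.5))
    # esw tends to sigma * sqrt(pi/2) as truncation grows
    esw_inf = m.effective_half_width(truncation_m=1e6).item()
    assert esw_inf == pytest.approx(25.0 * np.sqrt(np.pi / 2.0), rel=1e-10)
    # and esw is below both the truncation and the asymptote
    esw = m.effective_half_width().item()
    assert 0 < esw < min(150.0, esw_inf + 1e-9)


def test_sigma_recovery(rng):
    d = halfnormal_distances(rng, sigma=40.0, n=1500, w=120.0)
    m = HalfNormalDetectionFunction(truncation_m=120.0).fit(obs_frame(d))
    assert m.sigma().item() == pytest.approx(40.0, rel=0.06)
    assert m.k_ == 1 and m.n_ == 1500


def test_visibility_covariate_recovered_by_aic(rng):
    # two visibility classes with genuinely different scales
    d_open = halfnormal_distances(rng, 60.0, 800, 150.0)
    d_closed = halfnormal_distances(rng, 25.0, 800, 150.0)
    obs = pd.concat([obs_frame(d_open, visibility="open"),
                     obs_frame(d_closed, visibility="closed")],
                    ignore_index=True)
    best = fit_detection(obs, truncation_m=150.0)
    assert best.use_visibility
    s = best.sigma(obs.iloc[[0, 800]])
    assert s[0] > s[1]  # open-habitat scale larger


def test_fit_requires_enough_detections():
    with pytest.raises(ValueError):
        HalfNormalDetectionFunction(150.0).fit(obs_frame(np.full(10, 30.0)))
    with pytest.raises(ValueError):
        HalfNormalDetectionFunction(-5.0).fit(obs_frame(np.full(100, 30.0)))


def test_horvitz_thompson_segment_abundance():
    m = HalfNormalDetectionFunction(truncation_m=100.0)
    m.coef_ = np.array([np.log(50.0)])
    m.coef_names_ = ["log_sigma_0"]
    obs = obs_frame(np.array([10.0, 20.0, 500.0]), group_size=2.0)
    obs["segment_id"] = [0, 0, 1]  # third row beyond truncation -> dropped
    segments = pd.DataFrame({"segment_id": [0, 1], "x": [0.0, 0.0],
                             "y": [0.0, 450.0], "length_m": [450.0, 450.0]})
    out = segment_abundance(m, obs, segments)
    p = m.average_p().item()
    assert out.loc[0, "abundance"] == pytest.approx(4.0 / p)
    assert out.loc[1, "abundance"] == 0.0
    assert out["area_km2"].iloc[0] == pytest.approx(2 * 100.0 * 450.0 / 1e6)


def test_smoother_recovers_flat_field(rng):
    # constant true density 5 / km^2 over a 5 x 5 km area; with edf ~ 16
    # the surface noise is ~ 2 sqrt(edf / total count), so a total count of
    # ~4000 keeps 95% of cells within the 20% band tested here
    n = 400
    coords = rng.uniform(0, 5000, size=(n, 2))
    area = np.full(n, 2.0)
    counts = rng.poisson(5.0 * area)
    sm = DensitySmoother(n_knots=5).fit(coords, counts.astype(float), np.log(area))
    grid = Raster(np.zeros((20, 20)), cellsize=250.0)
    X, Y = grid.cell_centers()
    pred = sm.predict(np.column_stack([X.ravel(), Y.ravel()]))
    assert np.mean(np.abs(pred - 5.0) / 5.0 < 0.2) > 0.95


def test_smoother_finds_gradient(rng):
    n = 500
    coords = rng.uniform(0, 4000, size=(n, 2))
    true = 2.0 + 6.0 * coords[:, 1] / 4000.0      # south-north gradient
    area = np.full(n, 0.1)
    counts = rng.poisson(true * area)
    seg = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1],
                        "abundance": counts.astype(float), "area_km2": area})
    sm = fit_spatial_model(seg, n_knots=5)
    lo = sm.predict(np.array([[2000.0, 200.0]]))
    hi = sm.predict(np.array([[2000.0, 3800.0]]))
    assert hi.item() > lo.item() * 1.5


def test_predict_density_raster_has_cv(rng):
    n = 300
    coords = rng.uniform(0, 3000, size=(n, 2))
    area = np.full(n, 0.09)
    counts = rng.poisson(4.0 * area)
    sm = DensitySmoother(n_knots=4).fit(coords, counts.astype(float), np.log(area))
    grid = Raster(np.zeros((10, 10)), cellsize=300.0)
    dr = predict_density_raster(sm, grid, species="roe", year=2011,
                                n_draws=100, seed=5)
    assert np.all(dr.density.values >= 0)
    assert np.all(dr.cv.values >= 0) and np.nanmean(dr.cv.values) > 0
    # deterministic in the seed
    dr2 = predict_density_raster(sm, grid, species="roe", year=2011,
                                 n_draws=100, seed=5)
    np.testing.assert_array_equal(dr.cv.values, dr2.cv.values)


def _annual(years, base=2.0):
    g = Raster(np.zeros((4, 4)), cellsize=100.0)
    out = []
    for i, y in enumerate(years):
        out.append(DensityRaster(species="fallow", year=y,
                                 density=g.copy_with(np.full((4, 4), base + i)),
                                 cv=g.copy_with(np.full((4, 4), 0.1 * (i + 1)))))
    return out


def test_moving_average_windows():
    comps = moving_average_raster(_annual([2011, 2012, 2013, 2014]), window=3)
    assert [c.year for c in comps] == [(2011, 2013), (2012, 2014)]
    assert comps[0].density.values[0, 0] == pytest.approx(3.0)  # mean(2,3,4)
    assert comps[0].cv.values[0, 0] == pytest.approx(0.2)
    with pytest.raises(ValueError):
        moving_average_raster(_annual([2011, 2013, 2014]), window=2)
    with pytest.raises(ValueError):
        moving_average_raster(_annual([2011, 2012]), window=3)


def test_density_raster_validation():
    g = Raster(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        DensityRaster(species="roe", year=2011, density=g.copy_with([[1, -2], [0, 0]]))
    with pytest.raises(ValueError):
        DensityRaster(species="roe", year=2011, density=g,
                      cv=Raster(np.zeros((3, 3))))
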