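import numpy as np
import pandas as pd
import pytest

from deersem.density_surface import DensityRaster
from deersem.features import (
    DEFAULT_RADII,
    BufferExtractor,
    build_feature_table,
    extract_buffer_mean,
    fallow_composites,
    transform_and_screen,
)
from deersem.raster import Raster, disc_cell_indices


def test_extract_buffer_mean_matches_brute_force(rng):
    r = Raster(rng.uniform(0, 10, size=(30, 30)), cellsize=100.0)
    X, Y = r.cell_centers()
    for x, y, rad in [(1500.0, 1500.0, 500.0), (1240.0, 2010.0, 420.0)]:
        mask = (X - x) ** 2 + (Y - y) ** 2 <= rad**2
        want = r.values[mask].mean()
        assert extract_buffer_mean(r, (x, y), rad) == pytest.approx(want)


def test_buffer_extractor_matches_direct_calls(rng):
    grid = Raster(rng.uniform(0, 5, size=(25, 25)), cellsize=100.0)
    xs, ys = [600.0, 1200.0, 1800.0], [700.0, 1300.0, 1900.0]
    ex = BufferExtractor(grid, xs, ys, DEFAULT_RADII)
    m = ex.means(grid.values)
    for i, (x, y) in enumerate(zip(xs, ys)):
        for j, rad in enumerate(DEFAULT_RADII):
            assert m[i, j] == pytest.approx(extract_buffer_mean(grid, (x, y), rad))
    # restricted rows: others come back NaN
    m2 = ex.means(grid.values, rows=[1])
    assert np.isnan(m2[0]).all() and np.isnan(m2[2]).all()
    np.testing.assert_allclose(m2[1], m[1])


def _world(rng, years=(2011, 2012, 2013)):
    grid = Raster(rng.uniform(0.1, 0.9, size=(30, 30)), cellsize=100.0)

    def dr(sp, y, scale):
        vals = rng.uniform(1.0, 2.0, size=(30, 30)) * scale
        return DensityRaster(species=sp, year=y, density=grid.copy_with(vals),
                             cv=grid.copy_with(np.full((30, 30), 0.2)))

    roe = {y: dr("roe", y, 5.0) for y in years}
    munt = {y: dr("muntjac", y, 10.0) for y in years}
    fallow = {y: dr("fallow", y, 1.0) for y in years}
    return grid, roe, munt, fallow


def _culls(years=(2011, 2012, 2013)):
    rows = []
    for i, y in enumerate(years):
        rows += [
            {"id": f"a{i}", "year": y, "x": 1500.0, "y": 1500.0, "week": 2,
             "age_class": "adult", "body_mass_kg": 13.0, "embryo_count": 2,
             "block_id": 1},
            {"id": f"b{i}", "year": y, "x": 1400.0, "y": 1600.0, "week": 6,
             "age_class": "adult", "body_mass_kg": 14.0, "embryo_count": 1,
             "block_id": 2},
            {"id": f"c{i}", "year": y, "x": 1450.0, "y": 1450.0, "week": 20,
             "age_class": "adult", "body_mass_kg": 12.0, "embryo_count": 0,
             "block_id": 1},
            {"id": f"d{i}", "year": y, "x": 1500.0, "y": 1500.0, "week": 5,
             "age_class": "juvenile", "body_mass_kg": 9.0, "embryo_count": 0,
             "block_id": 1},
            {"id": f"e{i}", "year": y, "x": 1500.0, "y": 1500.0, "week": 5,
             "age_class": "adult", "body_mass_kg": 6.0, "embryo_count": 0,
             "block_id": 1},  # damaged carcass, below the 8 kg floor
        ]
    return pd.DataFrame(rows)


def test_build_feature_table_shapes_and_eligibility(rng):
    grid, roe, munt, fallow = _world(rng)
    culls = _culls()
    fal = fallow_composites(fallow)
    table = build_feature_table(culls, roe, munt, fal, grid)
    # 3 eligible per year x 3 years x 5 radii
    assert len(table) == 9 * len(DEFAULT_RADII)
    assert set(table["radius_m"]) == set(DEFAULT_RADII)
    # juveniles and sub-8-kg carcasses excluded
    assert not set(table["cull_id"]) & {"d0", "e0", "d1", "e1"}
    # fertility defined only inside weeks 1-12
    w20 = table[table["cull_id"] == "c0"]
    assert w20["fertility_binary"].isna().all()
    w2 = table[table["cull_id"] == "a0"]
    assert (w2["fertility_binary"] == 1.0).all()
    assert (w2["week_class"] == 0.0).all()
    w6 = table[table["cull_id"] == "b0"]
    assert (w6["fertility_binary"] == 0.0).all()
    assert (w6["week_class"] == 1.0).all()
    # arable is expressed in percent
    assert table["arable_pct"].between(0, 100).all()
    assert table["arable_pct"].max() > 1.0


def test_build_feature_table_uses_year_specific_rasters(rng):
    grid, roe, munt, fallow = _world(rng)
    culls = _culls()
    fal = fallow_composites(fallow)
    table = build_feature_table(culls, roe, munt, fal, grid)
    r = DEFAULT_RADII[0]
    a0 = table[(table["cull_id"] == "a0") & (table["radius_m"] == r)]
    a1 = table[(table["cull_id"] == "a1") & (table["radius_m"] == r)]
    # same location, different year -> different roe buffer mean
    assert float(a0["roe_density"].iloc[0]) != float(a1["roe_density"].iloc[0])
    rr, cc = disc_cell_indices(grid, 1500.0, 1500.0, r)
    want = roe[2011].density.values[rr, cc].mean()
    assert float(a0["roe_density"].iloc[0]) == pytest.approx(want)


def test_build_feature_table_errors(rng):
    grid, roe, munt, fallow = _world(rng)
    culls = _culls()
    fal = fallow_composites(fallow)
    with pytest.raises(ValueError, match="eligible"):
        build_feature_table(culls[culls["age_class"] != "adult"],
                            roe, munt, fal, grid)
    with pytest.raises(ValueError, match="missing density"):
        build_feature_table(culls, {2011: roe[2011]}, munt, fal, grid)


def test_fallow_composites_edge_years(rng):
    grid, _, _, fallow = _world(rng, years=(2011, 2012, 2013, 2014))
    fal = fallow_composites(fallow, window=3)
    assert fal[2011].year == (2011, 2013)   # edge year borrows nearest window
    assert fal[2012].year == (2011, 2013)
    assert fal[2013].year == (2012, 2014)
    assert fal[2014].year == (2012, 2014)


def test_transform_and_screen(rng):
    grid, roe, munt, fallow = _world(rng)
    table = build_feature_table(_culls(), roe, munt,
                                fallow_composites(fallow), grid)
    table, report = transform_and_screen(table)
    np.testing.assert_allclose(table["sqrt_fallow"],
                               np.sqrt(table["fallow_density"]))
    assert {"radius_m", "var_a", "var_b", "r", "flagged"} <= set(report.columns)
    # 6 unordered predictor pairs per radius
    assert len(report) == 6 * len(DEFAULT_RADII)


def test_screen_flags_collinear_pair():
    n = 40
    base = np.linspace(0, 1, n)
    table = pd.DataFrame({
        "radius_m": 400.0,
        "arable_pct": base * 100,
        "roe_density": base * 5 + 1,          # perfectly collinear with arable
        "muntjac_density": np.r_[base[n // 2:], base[: n // 2]] * 10,
        "fallow_density": np.random.default_rng(0).uniform(0.5, 1.5, n),
    })
    _, report = transform_and_screen(table)
    m = report[(report["var_a"] == "arable_pct") & (report["var_b"] == "roe_density")]
    assert bool(m["flagged"].iloc[0])
    assert float(m["r"].iloc[0]) == pytest.approx(1.0)
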