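"""Synthetic landscapes, density surfaces, surveys and cull records.

The generator emulates the statistical structure the analysis assumes: a
forest of contiguous blocks on a 100-m grid, an arable-extent field with
many zero cells and a long right tail, three deer density surfaces (the
introduced Fallow Deer concentrated along a monotone north-south gradient,
Reeve's Muntjac responding to arable extent and Fallow density, Roe Deer
varying smoothly), nocturnal line-transect surveys with half-normal
detection, and culled adult female Roe Deer whose body mass and twinning
probability respond to configurable effect sizes.  Every cull record is
tagged with its true buffer covariates so estimator-recovery tests can
compare fitted coefficients against the generating truth.

Spatial fields are sums of fixed large-scale gradients and Gaussian-filtered
white noise; densities are floored at zero after noise is added.  All
randomness flows from ``SimConfig.rng_seed`` through per-stage substreams,
so identical configurations reproduce outputs bit for bit regardless of the
order in which stages are called.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Raster, disc_cell_indices

__all__ = [
    "SimConfig",
    "TrueLandscape",
    "generate_landscape",
    "generate_density_surfaces",
    "default_transect_layout",
    "simulate_survey",
    "simulate_culls",
    "generate_world",
]

SPECIES = ("roe", "muntjac", "fallow")

# multiplicative effect of visibility class on the detection scale sigma
VISIBILITY_SIGMA_MULT = {"open": 1.3, "medium": 1.0, "dense": 0.7}


@dataclass
class SimConfig:
    """All knobs of the synthetic world.

    Defaults reproduce the study conditions: 14 forest blocks of mean area
    1,337 ha (SD 836), seven survey years, 492 adult female cull records,
    buffer-level arable extent averaging ~20%, and forest-wide mean
    densities of ~7.4 (Roe), ~15.1 (Muntjac) and ~1.2 (Fallow)
    individuals/km^2 with the Fallow surface strongly concentrated in the
    south.
    """

    # landscape
    n_blocks: int = 14
    block_area_mean_ha: float = 1337.0
    block_area_sd_ha: float = 836.0
    grid_cell_m: float = 100.0
    arable_amplitude: float = 1.0
    arable_threshold: float = 0.30          # on the standardised smooth field
    arable_corr_cells: float = 8.0
    # years / sampling
    years: tuple = (2011, 2012, 2013, 2014, 2015, 2016, 2017)
    n_culls: int = 492
    extra_nonadult_frac: float = 0.06
    frac_incomplete: float = 0.02           # damaged carcasses (mass < 8 kg)
    # survey / detection
    detection_sigma_m: float = 60.0
    truncation_m: float = 150.0
    transect_spacing_m: float = 500.0
    segment_length_m: float = 450.0
    group_size_mean: dict = field(default_factory=lambda: {"roe": 1.6, "muntjac": 1.2, "fallow": 5.0})
    group_size_sigma_exp: float = 0.12      # sigma multiplier (group size)^exp
    # density surfaces (individuals/km^2)
    roe_mean_density: float = 7.4
    muntjac_mean_density: float = 15.1
    fallow_mean_density: float = 1.2
    roe_noise_rel_sd: float = 0.40
    muntjac_noise_sd: float = 4.0
    density_corr_cells: float = 10.0
    year_rel_sd: float = 0.08               # smooth year-to-year multiplier
    fallow_south_fraction: float = 0.06     # share of the north-south span at high density
    fallow_texture_sd: float = 1.0          # lognormal across-easting texture
    # structural effect sizes (the generating truth)
    b_arable_mass: float = 1.3              # kg per unit arable fraction
    b_week_fert: float = 1.0                # logit, late vs early detectability
    b_roe_fert: float = 0.0                 # logit per SD of buffer Roe density
    b_muntjac_fert: float = 0.0             # logit per SD of buffer Muntjac density
    b_fallow_fert: float = 0.0              # logit per SD of sqrt buffer Fallow density
    b_mass_fert: float = 0.0                # logit per SD of body mass
    b_arable_fert: float = 0.0              # logit per SD of buffer arable %
    b_arable_muntjac: float = 4.0           # individuals/km^2 per unit arable fraction
    b_fallow_muntjac: float = -0.15         # per individual/km^2 of Fallow
    fert_intercept_p: float = 0.64          # twin probability at covariate means
    # individual-level noise
    mass_mean_kg: float = 13.7
    sigma_mass: float = 1.40
    block_sd_mass: float = 0.30
    block_sd_fert: float = 0.20
    year_sd_fert: float = 0.10
    true_buffer_radius_m: float = 500.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_blocks <= 0:
            raise ValueError("n_blocks must be positive")
        if self.grid_cell_m <= 0 or self.block_area_mean_ha <= 0:
            raise ValueError("grid cell size and block areas must be positive")
        if self.truncation_m < 0:
            raise ValueError("truncation must be non-negative")
        if self.n_culls <= 0:
            raise ValueError("n_culls must be positive")
        if min(self.roe_mean_density, self.muntjac_mean_density, self.fallow_mean_density) < 0:
            raise ValueError("baseline densities must be non-negative")
        ys = list(self.years)
        if any(b - a != 1 for a, b in zip(ys, ys[1:])):
            raise ValueError("years must be consecutive")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent substream for a pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence((self.rng_seed, stage)))


@dataclass
class TrueLandscape:
    """Shared-grid rasters: arable fraction, block labels, true densities."""

    arable: Raster                                  # fraction in [0, 1]
    blocks: Raster                                  # integer labels 0..n-1
    densities: dict = field(default_factory=dict)   # (species, year) -> Raster

    def __post_init__(self) -> None:
        if not self.arable.same_grid(self.blocks):
            raise ValueError("arable and block rasters are misaligned")
        a = self.arable.values
        if np.nanmin(a) < -1e-12 or np.nanmax(a) > 1 + 1e-12:
            raise ValueError("arable fraction must lie in [0, 1]")

    def density(self, species: str, year: int) -> Raster:
        return self.densities[(species, year)]


def _smooth_field(rng: np.random.Generator, shape, corr_cells: float) -> np.ndarray:
    """Standardised Gaussian-filtered white noise (mean 0, SD 1)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), corr_cells, mode="reflect")
    return (f - f.mean()) / max(f.std(), 1e-12)


def generate_landscape(config: SimConfig) -> TrueLandscape:
    """Blocks (power-diagram partition, hence contiguous) and arable field.

    The grid is sized so that total area = n_blocks * mean block area, which
    pins the realised mean block area; a power diagram with jittered weights
    spreads the individual areas around it.
    """
    config.validate()
    rng = config.rng(1)
    cell_ha = (config.grid_cell_m / 100.0) ** 2
    total_cells = config.n_blocks * config.block_area_mean_ha / cell_ha
    side = int(np.ceil(np.sqrt(total_cells)))
    shape = (side, side)

    # blocks: additively weighted (power) Voronoi -> convex, contiguous cells
    seeds = rng.uniform(0.08, 0.92, size=(config.n_blocks, 2)) * side
    target = rng.normal(config.block_area_mean_ha, config.block_area_sd_ha, config.n_blocks)
    target = np.clip(target, 0.2 * config.block_area_mean_ha, None)
    w = (target - target.mean()) / cell_ha  # weight in cell^2 units
    ii, jj = np.mgrid[0:side, 0:side]
    d2 = ((ii[..., None] + 0.5 - seeds[:, 1]) ** 2
          + (jj[..., None] + 0.5 - seeds[:, 0]) ** 2)
    # shrink weights until no block is swallowed by its neighbours
    for _ in range(20):
        blocks = np.argmin(d2 - w, axis=-1).astype(float)
        if len(np.unique(blocks)) == config.n_blocks:
            break
        w *= 0.6

    f = _smooth_field(rng, shape, config.arable_corr_cells)
    arable = np.clip(config.arable_amplitude * (f - config.arable_threshold), 0.0, 1.0)

    cs = config.grid_cell_m
    return TrueLandscape(
        arable=Raster(arable, cellsize=cs),
        blocks=Raster(blocks, cellsize=cs),
    )


def generate_density_surfaces(landscape: TrueLandscape, config: SimConfig) -> TrueLandscape:
    """Fill per-species, per-year true density rasters (individuals/km^2).

    Fallow: a monotone north-south logistic gradient (high in the south)
    modulated by an across-easting lognormal texture, rescaled to the target
    forest-wide mean -- reproducing a low mean with a long right tail.
    Muntjac: baseline + arable and Fallow effects + smooth noise, floored at
    zero.  Roe: smooth multiplicative variation around its mean.  Years get
    independent smooth multipliers around 1.
    """
    config.validate()
    rng = config.rng(2)
    shape = landscape.arable.shape
    nrows, ncols = shape
    cs = landscape.arable.cellsize

    yfrac = (np.arange(nrows)[:, None] + 0.5) / nrows  # 0 at south edge
    south = 1.0 / (1.0 + np.exp((yfrac - config.fallow_south_fraction)
                                / max(0.02, config.fallow_south_fraction / 3.0)))
    texture = np.exp(config.fallow_texture_sd
                     * _smooth_field(rng, (ncols,), config.density_corr_cells))[None, :]
    fallow_base = south * texture
    mean_now = fallow_base.mean()
    if config.fallow_mean_density > 0 and mean_now > 0:
        fallow_base *= config.fallow_mean_density / mean_now
    else:
        fallow_base[:] = 0.0

    roe_field = _smooth_field(rng, shape, config.density_corr_cells)
    muntjac_noise = _smooth_field(rng, shape, config.density_corr_cells)
    arable = landscape.arable.values

    densities = {}
    for year in config.years:
        ymult = {s: max(0.0, 1.0 + config.year_rel_sd * rng.standard_normal())
                 for s in SPECIES}
        fallow = fallow_base * ymult["fallow"]
        roe = np.clip(config.roe_mean_density
                      * (1.0 + config.roe_noise_rel_sd * roe_field)
                      * ymult["roe"], 0.0, None)
        muntjac_base = (config.muntjac_mean_density
                        - config.b_arable_muntjac * arable.mean()
                        - config.b_fallow_muntjac * fallow_base.mean())
        muntjac = np.clip((muntjac_base
                           + config.b_arable_muntjac * arable
                           + config.b_fallow_muntjac * fallow
                           + config.muntjac_noise_sd * muntjac_noise)
                          * ymult["muntjac"], 0.0, None)
        densities[("roe", year)] = Raster(roe, cellsize=cs)
        densities[("muntjac", year)] = Raster(muntjac, cellsize=cs)
        densities[("fallow", year)] = Raster(fallow, cellsize=cs)
    landscape.densities = densities
    return landscape


def default_transect_layout(landscape: TrueLandscape, config: SimConfig) -> pd.DataFrame:
    """North-south transect lines split into fixed-length segments.

    Each segment gets a visibility class (a stand-age proxy) drawn once; the
    layout itself is deterministic given the config seed.
    """
    rng = config.rng(3)
    xmin, ymin, xmax, ymax = landscape.arable.extent
    xs = np.arange(xmin + config.transect_spacing_m / 2.0, xmax, config.transect_spacing_m)
    seg_len = config.segment_length_m
    rows = []
    sid = 0
    for ti, x in enumerate(xs):
        y = ymin
        while y + seg_len <= ymax:
            rows.append({
                "segment_id": sid, "transect": ti,
                "x": float(x), "y": float(y + seg_len / 2.0),
                "length_m": float(seg_len),
                "visibility_class": ["open", "medium", "dense"][rng.integers(0, 3)],
            })
            sid += 1
            y += seg_len
    return pd.DataFrame(rows)


def simulate_survey(
    landscape: TrueLandscape,
    transects: pd.DataFrame,
    config: SimConfig,
    species: tuple = SPECIES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate distance-sampling detections along transect segments.

    Animals are placed by an inhomogeneous Poisson draw (in groups) from the
    true surface within each strip; a group at perpendicular distance d is
    detected with probability exp(-d^2 / 2 sigma_v^2), where sigma_v is the
    base detection scale times the segment's visibility multiplier times
    (group size)^exp.

    Returns (observations, strip_truth); strip_truth holds the simulated
    number of animals per (species, year, segment) so conservation checks
    (detections <= animals present) can be made exactly.
    """
    if len(transects) == 0:
        raise ValueError("empty transect layout")
    if not landscape.densities:
        raise ValueError("landscape has no density surfaces")
    if config.detection_sigma_m <= 0:
        raise ValueError("detection_sigma_m must be positive")
    rng = config.rng(4)
    w = config.truncation_m
    seg_area_km2 = 2.0 * w * transects["length_m"].to_numpy() / 1e6

    obs_rows, truth_rows = [], []
    for sp in species:
        gmean = config.group_size_mean.get(sp, 1.5)
        for year in config.years:
            dens = landscape.density(sp, year)
            d_at_seg = np.array([
                dens.values[dens.index_of(x, y)]
                for x, y in zip(transects["x"], transects["y"])
            ])
            lam_groups = d_at_seg * seg_area_km2 / gmean
            n_groups = rng.poisson(lam_groups)
            for (seg, ng) in zip(transects.itertuples(), n_groups):
                vis_mult = VISIBILITY_SIGMA_MULT[seg.visibility_class]
                n_animals = 0
                for _ in range(int(ng)):
                    size = 1 + rng.poisson(max(gmean - 1.0, 0.0))
                    n_animals += size
                    d = rng.uniform(0.0, w)
                    sigma = (config.detection_sigma_m * vis_mult
                             * size**config.group_size_sigma_exp)
                    p = 1.0 if not np.isfinite(sigma) else float(np.exp(-d**2 / (2.0 * sigma**2)))
                    if rng.uniform() < p:
                        obs_rows.append({
                            "species": sp, "year": year,
                            "segment_id": seg.segment_id,
                            "perpendicular_distance": float(d),
                            "group_size": int(size),
                            "visibility_class": seg.visibility_class,
                            "x": seg.x, "y": seg.y,
                        })
                truth_rows.append({"species": sp, "year": year,
                                   "segment_id": seg.segment_id,
                                   "n_animals": n_animals})
    obs = pd.DataFrame(obs_rows, columns=[
        "species", "year", "segment_id", "perpendicular_distance",
        "group_size", "visibility_class", "x", "y",
    ])
    return obs, pd.DataFrame(truth_rows)


def _buffer_mean(raster: Raster, x: float, y: float, radius: float) -> float:
    rr, cc = disc_cell_indices(raster, x, y, radius)
    return float(raster.values[rr, cc].mean())


def simulate_culls(landscape: TrueLandscape, config: SimConfig) -> pd.DataFrame:
    """Simulate culled female Roe Deer with known structural effects.

    Locations are sampled proportional to the year's true Roe density
    (stalking happens where deer are), weeks are uniform over 1-12, body
    mass responds to buffer arable extent, and the twinning probability
    follows a logistic model in the week class and the standardised true
    buffer covariates.  Effect sizes are per SD so they can be compared
    directly with standardised fitted coefficients.
    """
    config.validate()
    if not landscape.densities:
        raise ValueError("landscape has no density surfaces")
    rng = config.rng(5)
    n_adult = config.n_culls
    n_nonadult = int(round(config.extra_nonadult_frac * n_adult))
    n_damaged = int(round(config.frac_incomplete * n_adult))
    n_total = n_adult + n_nonadult + n_damaged

    cs = landscape.arable.cellsize
    nrows, ncols = landscape.arable.shape
    years = np.asarray(config.years)

    recs = []
    for i in range(n_total):
        year = int(years[rng.integers(0, len(years))])
        roe = landscape.density("roe", year).values
        pcell = roe.ravel() / roe.sum()
        cell = rng.choice(roe.size, p=pcell)
        r, c = np.unravel_index(cell, roe.shape)
        x = (c + rng.uniform()) * cs
        y = (r + rng.uniform()) * cs
        recs.append({"id": i, "x": float(x), "y": float(y), "year": year,
                     "week": int(rng.integers(1, 13)),
                     "block_id": int(landscape.blocks.values[r, c])})
    culls = pd.DataFrame(recs)

    radius = config.true_buffer_radius_m
    fallow_mean_by_year = {
        y: np.mean([landscape.density("fallow", yy).values
                    for yy in years[np.abs(years - y) <= 1]], axis=0)
        for y in years
    }
    buf = {k: np.empty(n_total) for k in ("arable", "roe", "muntjac", "fallow")}
    for i, rec in culls.iterrows():
        x, y, year = rec["x"], rec["y"], int(rec["year"])
        buf["arable"][i] = _buffer_mean(landscape.arable, x, y, radius)
        buf["roe"][i] = _buffer_mean(landscape.density("roe", year), x, y, radius)
        buf["muntjac"][i] = _buffer_mean(landscape.density("muntjac", year), x, y, radius)
        fr = Raster(fallow_mean_by_year[year], cellsize=cs)
        buf["fallow"][i] = _buffer_mean(fr, x, y, radius)
    culls["true_arable_buffer"] = buf["arable"]
    culls["true_roe_buffer"] = buf["roe"]
    culls["true_muntjac_buffer"] = buf["muntjac"]
    culls["true_fallow_buffer"] = buf["fallow"]

    # age classes: first n_adult rows adult, then the extras
    age = np.array(["adult"] * n_adult
                   + list(rng.choice(["juvenile", "yearling"], size=n_nonadult))
                   + ["adult"] * n_damaged)
    culls["age_class"] = age

    block_eff_mass = rng.normal(0.0, config.block_sd_mass, config.n_blocks)
    mass = (config.mass_mean_kg
            + config.b_arable_mass * culls["true_arable_buffer"].to_numpy()
            + block_eff_mass[culls["block_id"].to_numpy()]
            + rng.normal(0.0, config.sigma_mass, n_total))
    mass = np.maximum(mass, 8.5)
    if n_damaged:
        mass[-n_damaged:] = rng.uniform(5.0, 7.9, n_damaged)  # incomplete carcasses
    nonadult = slice(n_adult, n_adult + n_nonadult)
    mass[nonadult] = np.maximum(mass[nonadult] - 3.0, 6.0)
    culls["body_mass_kg"] = np.round(mass, 1)

    def z(v):
        s = np.std(v, ddof=1)
        return (v - np.mean(v)) / s if s > 0 else np.zeros_like(v)

    block_eff_fert = rng.normal(0.0, config.block_sd_fert, config.n_blocks)
    year_eff_fert = {int(y): rng.normal(0.0, config.year_sd_fert) for y in years}
    a0 = np.log(config.fert_intercept_p / (1.0 - config.fert_intercept_p))
    eta = (a0
           + config.b_week_fert * (culls["week"].to_numpy() >= 4)
           - config.b_week_fert * np.mean(culls["week"].to_numpy() >= 4)
           + config.b_roe_fert * z(culls["true_roe_buffer"].to_numpy())
           + config.b_muntjac_fert * z(culls["true_muntjac_buffer"].to_numpy())
           + config.b_fallow_fert * z(np.sqrt(culls["true_fallow_buffer"].to_numpy()))
           + config.b_arable_fert * z(culls["true_arable_buffer"].to_numpy())
           + config.b_mass_fert * z(culls["body_mass_kg"].to_numpy())
           + block_eff_fert[culls["block_id"].to_numpy()]
           + np.array([year_eff_fert[int(y)] for y in culls["year"]]))
    p_twin = 1.0 / (1.0 + np.exp(-eta))
    twin = rng.uniform(size=n_total) < p_twin
    singles = rng.uniform(size=n_total) < 0.75  # one vs zero embryos when not twinning
    culls["embryo_count"] = np.where(twin, 2, np.where(singles, 1, 0))
    culls["corpora_lutea"] = np.minimum(
        culls["embryo_count"] + (rng.uniform(size=n_total) < 0.15), 2
    ).astype(int)
    return culls


def generate_world(config: SimConfig) -> tuple[TrueLandscape, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience: landscape + densities + survey + culls in one call."""
    land = generate_landscape(config)
    generate_density_surfaces(land, config)
    transects = default_transect_layout(land, config)
    obs, truth = simulate_survey(land, transects, config)
    culls = simulate_culls(land, config)
    return land, transects, obs, culls
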