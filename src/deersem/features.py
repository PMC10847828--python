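"""Buffer-radius covariate extraction around cull locations.

For each eligible cull record and each candidate home-range radius (400-600
m by 50-m steps), the mean of every density surface and the arable extent
are averaged over the raster cells whose centres fall within the closed
disc around the cull location (centre-in-disc rule; differences from
area-weighted overlap are sub-cell at 100-m resolution against 400-600 m
radii).  Roe and Muntjac densities come from the year-specific rasters;
Fallow from the 3-year sliding-mean composite centred on the cull year
(edge years use the nearest available window).

Eligibility: adults with complete carcasses (dressed mass >= 8 kg).  The
twinning response (1 = two embryos, 0 = one or zero) only exists for culls
in the embryo-detectability window (weeks 1-12, i.e. January-March), with
the week class coded 0 for weeks 1-3 and 1 for weeks 4-12; body-mass rows
keep the continuous week covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density_surface import DensityRaster, moving_average_raster
from .raster import Raster, disc_cell_indices

__all__ = [
    "DEFAULT_RADII",
    "BufferExtractor",
    "extract_buffer_mean",
    "fallow_composites",
    "build_feature_table",
    "transform_and_screen",
]

DEFAULT_RADII = (400.0, 450.0, 500.0, 550.0, 600.0)

PREDICTORS = ("arable_pct", "roe_density", "muntjac_density", "sqrt_fallow")


def extract_buffer_mean(raster: Raster, point: tuple[float, float], radius_m: float) -> float:
    """Mean raster value over cells whose centres lie within the disc."""
    rr, cc = disc_cell_indices(raster, point[0], point[1], radius_m)
    return float(raster.values[rr, cc].mean())


class BufferExtractor:
    """Precomputed disc memberships for repeated extraction.

    The uncertainty propagation re-extracts buffer means from hundreds of
    perturbed rasters on the same grid, so the (point x radius) cell index
    sets are computed once.
    """

    def __init__(self, grid: Raster, xs, ys, radii=DEFAULT_RADII):
        self.grid = grid
        self.radii = tuple(float(r) for r in radii)
        self._flat: list[list[np.ndarray]] = []
        ncols = grid.ncols
        for x, y in zip(xs, ys):
            per_radius = []
            for r in self.radii:
                rr, cc = disc_cell_indices(grid, float(x), float(y), r)
                per_radius.append(rr * ncols + cc)
            self._flat.append(per_radius)

    def means(self, values: np.ndarray, rows=None) -> np.ndarray:
        """(n_points, n_radii) buffer means of a value grid on this grid.

        ``rows`` restricts the computation to those point indices; other
        rows of the returned array are NaN.
        """
        flat = np.asarray(values, dtype=float).ravel()
        out = np.full((len(self._flat), len(self.radii)), np.nan)
        indices = range(len(self._flat)) if rows is None else rows
        for i in indices:
            per_radius = self._flat[i]
            for j, idx in enumerate(per_radius):
                out[i, j] = flat[idx].mean()
        return out


def fallow_composites(annual: dict[int, DensityRaster], window: int = 3) -> dict[int, DensityRaster]:
    """Map each year to its 3-year sliding-mean composite, centred on the
    year; first/last years use the nearest available window."""
    years = sorted(annual)
    comps = moving_average_raster([annual[y] for y in years], window)
    centers = [int(np.mean(c.year)) for c in comps]
    out = {}
    for y in years:
        nearest = int(np.argmin([abs(y - c) for c in centers]))
        out[y] = comps[nearest]
    return out


def _eligible(culls: pd.DataFrame) -> pd.DataFrame:
    d = culls[(culls["age_class"] == "adult") & (culls["body_mass_kg"] >= 8.0)]
    return d.reset_index(drop=True)


def build_feature_table(
    culls: pd.DataFrame,
    roe: dict[int, DensityRaster],
    muntjac: dict[int, DensityRaster],
    fallow_by_year: dict[int, DensityRaster],
    arable: Raster,
    radii=DEFAULT_RADII,
    extractor: BufferExtractor | None = None,
) -> pd.DataFrame:
    """Long-format feature table: one row per (eligible record x radius).

    ``fallow_by_year`` maps each cull year to its composite raster (see
    :func:`fallow_composites`).  Pass a prebuilt ``extractor`` (on the
    eligible records, in order) to skip the disc geometry; this is how the
    resampling loop avoids recomputing it.
    """
    d = _eligible(culls)
    if len(d) == 0:
        raise ValueError("no eligible cull records (adult, mass >= 8 kg)")
    missing = sorted({int(y) for y in d["year"]} - set(roe) |
                     {int(y) for y in d["year"]} - set(muntjac) |
                     {int(y) for y in d["year"]} - set(fallow_by_year))
    if missing:
        raise ValueError(f"missing density rasters for year(s): {missing}")

    if extractor is None:
        extractor = BufferExtractor(arable, d["x"].to_numpy(), d["y"].to_numpy(), radii)
    arable_means = extractor.means(arable.values)

    n, nr = len(d), len(extractor.radii)
    roe_m = np.empty((n, nr))
    munt_m = np.empty((n, nr))
    fal_m = np.empty((n, nr))
    for year, idx in d.groupby("year").groups.items():
        rows = np.asarray(list(idx))
        # per-year extraction reuses the shared disc indices
        roe_m[rows] = extractor.means(roe[int(year)].density.values, rows)[rows]
        munt_m[rows] = extractor.means(muntjac[int(year)].density.values, rows)[rows]
        fal_m[rows] = extractor.means(fallow_by_year[int(year)].density.values, rows)[rows]

    week = d["week"].to_numpy()
    fert = np.where(d["embryo_count"].to_numpy() == 2, 1.0, 0.0)
    in_window = (week >= 1) & (week <= 12)
    fert = np.where(in_window, fert, np.nan)

    frames = []
    for j, r in enumerate(extractor.radii):
        frames.append(pd.DataFrame({
            "cull_id": d["id"].to_numpy(),
            "radius_m": r,
            "arable_pct": arable_means[:, j] * 100.0,
            "roe_density": roe_m[:, j],
            "muntjac_density": munt_m[:, j],
            "fallow_density": fal_m[:, j],
            "week": week,
            "week_class": (week >= 4).astype(float),
            "year": d["year"].to_numpy(),
            "block_id": d["block_id"].to_numpy(),
            "body_mass_kg": d["body_mass_kg"].to_numpy(),
            "fertility_binary": fert,
        }))
    table = pd.concat(frames, ignore_index=True)
    return table


def transform_and_screen(table: pd.DataFrame, r_threshold: float = 0.78):
    """Add the square-root Fallow predictor and screen for collinearity.

    Returns (table, report): the report lists every predictor pair at every
    radius with its Pearson r; pairs with \|r\| above the threshold are
    flagged (flagging only -- nothing is dropped).
    """
    table = table.copy()
    table["sqrt_fallow"] = np.sqrt(table["fallow_density"])
    rows = []
    for radius, g in table.groupby("radius_m"):
        for i, a in enumerate(PREDICTORS):
            for b in PREDICTORS[i + 1:]:
                x, y = g[a].to_numpy(), g[b].to_numpy()
                if np.std(x) == 0 or np.std(y) == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                rows.append({"radius_m": radius, "var_a": a, "var_b": b,
                             "r": r, "flagged": bool(abs(r) > r_threshold)
                             if np.isfinite(r) else False})
    report = pd.DataFrame(rows)
    return table, report
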