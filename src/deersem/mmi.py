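"""Multimodel inference across candidate subsets and buffer radii, with
propagation of density-surface uncertainty.

For each SEM component, every subset of its candidate predictors (controls
always retained) is fitted at every buffer radius; the resulting models are
weighted by AICc jointly over subsets x radii, yielding

* an 85% confidence set (smallest weight-ranked prefix reaching 0.85),
* full (zero-substitution) model-averaged coefficients with unconditional
  standard errors and normal-theory 95% CIs,
* per-predictor importance (summed weight of models containing it), and
* the Akaike-weighted mean buffer radius with its weighted SD.

Density uncertainty is propagated by repeating the whole chain on rasters
resampled cell-wise from a mean-preserving lognormal whose coefficient of
variation equals the mapped CV; final coefficients and CI bounds are the
arithmetic means across iterations, with percentile CIs archived alongside.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateModel",
    "ComponentAverage",
    "AveragingResult",
    "aicc",
    "akaike_weights",
    "enumerate_models",
    "confidence_set",
    "model_average",
    "resample_density_raster",
    "propagate",
    "compare_effect_strengths",
]

_MAX_CANDIDATES = 12  # guard: 2^12 subsets per radius is the enumeration cap


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1); undefined for n <= k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aiccs) -> np.ndarray:
    """Normalised relative likelihoods exp(-delta/2) / sum."""
    a = np.asarray(aiccs, dtype=float)
    if a.size == 0 or not np.any(np.isfinite(a)):
        raise ValueError("need at least one finite AICc")
    delta = a - np.nanmin(a[np.isfinite(a)])
    rel = np.where(np.isfinite(delta), np.exp(-0.5 * delta), 0.0)
    return rel / rel.sum()


def enumerate_models(candidates: list[str], radii) -> list[tuple[tuple[str, ...], float]]:
    """All 2^p candidate subsets crossed with all radii.

    Controls are implicit (always included at fit time), so the empty subset
    denotes the controls-only model.
    """
    if len(candidates) > _MAX_CANDIDATES:
        raise ValueError(f"{len(candidates)} candidates exceeds the enumeration guard "
                         f"({_MAX_CANDIDATES})")
    subsets = []
    for r in range(len(candidates) + 1):
        subsets.extend(itertools.combinations(candidates, r))
    return [(s, float(rad)) for rad in radii for s in subsets]


@dataclass
class CandidateModel:
    """One fitted candidate: a predictor subset at one buffer radius."""

    component: str
    subset: tuple[str, ...]
    radius_m: float
    loglik: float
    k: int
    n: int
    coefs: dict[str, float]
    ses: dict[str, float]
    std_coefs: dict[str, float] = field(default_factory=dict)
    aicc: float = np.nan
    weight: float = np.nan


def confidence_set(models: list[CandidateModel], level: float = 0.85) -> list[CandidateModel]:
    """Smallest weight-ranked prefix whose cumulative weight reaches ``level``."""
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    ranked = sorted(models, key=lambda m: -m.weight)
    out, cum = [], 0.0
    for m in ranked:
        out.append(m)
        cum += m.weight
        if cum >= level - 1e-12:
            break
    return out


@dataclass
class ComponentAverage:
    """Single-iteration averaging result for one component."""

    component: str
    table: pd.DataFrame            # index: predictor; estimate, se, ci_lo, ci_hi,
                                   # importance, in_set; std_estimate
    weighted_mean_radius: float
    weighted_radius_sd: float
    n_models: int
    best_aicc: float


def model_average(
    models: list[CandidateModel],
    predictors: list[str],
    level: float = 0.85,
    method: str = "full",
) -> ComponentAverage:
    """Weight candidates by AICc and average coefficients.

    ``method="full"`` substitutes zero (with zero SE) in models excluding a
    predictor, shrinking weakly supported effects toward zero;
    ``method="natural"`` renormalises over containing models only.
    Unconditional SEs use the weighted combination of within-model SEs and
    between-model deviations.
    """
    if method not in {"full", "natural"}:
        raise ValueError(f"unknown averaging method {method!r}")
    w = akaike_weights([m.aicc for m in models])
    for m, wi in zip(models, w):
        m.weight = float(wi)
    cset = confidence_set(models, level)
    in_set_preds = set().union(*(set(m.subset) for m in cset)) if cset else set()

    radii = np.array([m.radius_m for m in models])
    rbar = float(np.sum(w * radii))
    rsd = float(np.sqrt(np.sum(w * (radii - rbar) ** 2)))

    def _avg(ww, beta, se, sbeta):
        bbar = float(np.sum(ww * beta))
        se_u = float(np.sum(ww * np.sqrt(se**2 + (beta - bbar) ** 2)))
        return bbar, se_u, float(np.sum(ww * sbeta))

    rows = []
    for pred in predictors:
        beta = np.array([m.coefs.get(pred, 0.0) for m in models])
        se = np.array([m.ses.get(pred, 0.0) for m in models])
        sbeta = np.array([m.std_coefs.get(pred, 0.0) for m in models])
        contains = np.array([pred in m.subset for m in models])
        importance = float(np.sum(w[contains]))
        # both conventions are computed on every call (the cost is only
        # arithmetic over already-fitted models); ``method`` selects which
        # one fills the headline estimate/se/ci columns, while the natural
        # average is always reported under its own columns as the
        # effect-size estimate conditional on the predictor being active
        full = _avg(w, beta, se, sbeta)
        if importance > 0:
            wn = np.where(contains, w, 0.0) / importance
            nat = _avg(wn, np.where(contains, beta, 0.0),
                       np.where(contains, se, 0.0),
                       np.where(contains, sbeta, 0.0))
        else:
            nat = (0.0, 0.0, 0.0)
        bbar, se_u, sbar = full if method == "full" else nat
        rows.append({
            "predictor": pred,
            "estimate": bbar,
            "se": se_u,
            "ci_lo": bbar - 1.96 * se_u,
            "ci_hi": bbar + 1.96 * se_u,
            "importance": importance,
            "in_set": pred in in_set_preds,
            "std_estimate": sbar,
            "natural_estimate": nat[0],
            "natural_se": nat[1],
            "natural_ci_lo": nat[0] - 1.96 * nat[1],
            "natural_ci_hi": nat[0] + 1.96 * nat[1],
        })
    table = pd.DataFrame(rows).set_index("predictor")
    return ComponentAverage(
        component=models[0].component if models else "",
        table=table,
        weighted_mean_radius=rbar,
        weighted_radius_sd=rsd,
        n_models=len(models),
        best_aicc=float(min(m.aicc for m in models)),
    )


def resample_density_raster(density_raster, rng_or_seed):
    """Draw a perturbed copy of a density raster from its mapped uncertainty.

    Each cell is resampled from a lognormal with mean equal to the cell's
    density estimate and coefficient of variation equal to the cell's CV
    (sigma_ln^2 = ln(1 + CV^2), mu_ln = ln m - sigma_ln^2 / 2, so the draw is
    mean-preserving on the natural scale).  Cells with CV = 0 or density 0
    are returned unchanged.
    """
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) \
        else np.random.default_rng(rng_or_seed)
    dens = density_raster.density.values
    cv = density_raster.cv.values
    if cv is None:
        raise ValueError("density raster has no CV grid")
    out = dens.copy()
    mask = (cv > 0) & (dens > 0) & np.isfinite(dens) & np.isfinite(cv)
    m = dens[mask]
    c = cv[mask]
    s2 = np.log1p(c**2)
    mu = np.log(m) - s2 / 2.0
    draws = rng.lognormal(mean=mu, sigma=np.sqrt(s2))
    out[mask] = draws
    return density_raster.copy_with_density(out)


@dataclass
class AveragingResult:
    """Final propagated result: one table per component plus the archive."""

    components: dict[str, pd.DataFrame]       # estimate/se/CI means across iters
    weighted_mean_radius: float               # across components and iterations
    weighted_radius_sd: float
    n_iterations: int
    n_failed: int
    archive: pd.DataFrame                     # per iteration x component x predictor

    def supported(self, component: str) -> pd.Series:
        t = self.components[component]
        return t["in_set"] & ((t["ci_lo"] > 0) | (t["ci_hi"] < 0))


def propagate(pipeline, n_iter: int = 100, seed: int = 0,
              max_failure_frac: float = 0.2) -> AveragingResult:
    """Run the resample -> extract -> fit -> weight -> average chain
    ``n_iter`` times and combine.

    ``pipeline`` is a callable taking a per-iteration integer seed and
    returning ``dict[component] -> ComponentAverage`` (with CV = 0 inputs the
    chain is deterministic and a single iteration reproduces the plain fit).
    Failed iterations are logged and skipped; more than ``max_failure_frac``
    failures aborts.
    """
    rng = np.random.default_rng(seed)
    iter_seeds = rng.integers(0, 2**31 - 1, size=n_iter)
    records = []
    radius_rows = []
    n_failed = 0
    for it, s in enumerate(iter_seeds):
        try:
            result = pipeline(int(s))
        except Exception as e:  # noqa: BLE001 -- any stage may fail on a bad draw
            n_failed += 1
            logger.warning("iteration %d failed: %s", it, e)
            if n_failed > max_failure_frac * n_iter:
                raise RuntimeError(
                    f"{n_failed}/{it + 1} propagation iterations failed; aborting"
                ) from e
            continue
        for comp, avg in result.items():
            radius_rows.append({"iteration": it, "component": comp,
                                "wmean_radius": avg.weighted_mean_radius,
                                "wsd_radius": avg.weighted_radius_sd})
            for pred, row in avg.table.iterrows():
                rec = {"iteration": it, "component": comp, "predictor": pred}
                rec.update(row.to_dict())
                records.append(rec)
    if not records:
        raise RuntimeError("no propagation iteration succeeded")
    archive = pd.DataFrame(records)
    rad = pd.DataFrame(radius_rows)

    components = {}
    for comp, g in archive.groupby("component"):
        agg = g.groupby("predictor").agg(
            estimate=("estimate", "mean"),
            se=("se", "mean"),
            ci_lo=("ci_lo", "mean"),
            ci_hi=("ci_hi", "mean"),
            importance=("importance", "mean"),
            in_set=("in_set", "mean"),
            std_estimate=("std_estimate", "mean"),
            natural_estimate=("natural_estimate", "mean"),
            natural_se=("natural_se", "mean"),
            natural_ci_lo=("natural_ci_lo", "mean"),
            natural_ci_hi=("natural_ci_hi", "mean"),
            pct_lo=("estimate", lambda v: float(np.percentile(v, 2.5))),
            pct_hi=("estimate", lambda v: float(np.percentile(v, 97.5))),
        )
        agg["in_set"] = agg["in_set"] > 0.5
        agg["supported"] = agg["in_set"] & ((agg["ci_lo"] > 0) | (agg["ci_hi"] < 0))
        components[comp] = agg

    per_iter_radius = rad.groupby("iteration")["wmean_radius"].mean()
    wmr = float(per_iter_radius.mean())
    wsd = float(rad["wsd_radius"].mean())
    return AveragingResult(
        components=components,
        weighted_mean_radius=wmr,
        weighted_radius_sd=wsd,
        n_iterations=n_iter - n_failed,
        n_failed=n_failed,
        archive=archive,
    )


def compare_effect_strengths(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test on two samples of effect magnitudes.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
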