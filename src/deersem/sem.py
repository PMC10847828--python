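"""Piecewise structural equation model: the four component regressions.

The causal diagram relates, within a buffer around each cull location:

* Reeve's Muntjac density  <- arable extent + sqrt(Fallow density)   (gaussian)
* Roe Deer density         <- arable extent + sqrt(Fallow density)   (gaussian)
* Roe Deer body mass (kg)  <- arable + Roe + Muntjac + sqrt(Fallow)  (gaussian,
      calendar week always included as a continuous control)
* Roe Deer fertility (P[two embryos] vs one/zero) <- body mass + arable +
      Roe + Muntjac + sqrt(Fallow)                                  (binomial,
      the early/late-week detectability class always included as control)

The Roe/Muntjac density pair shares habitat drivers, which is acknowledged
as a correlated error (residual correlation) rather than a directed path.
Each component is fitted by ML with crossed random intercepts (forest block
and/or cull year), the structure being chosen beforehand by AICc on the full
fixed model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:  # sklearn is used only for its estimator protocol
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore
        pass

from .mixedmodels import FitError, MixedModelFit, fit_mixed_model
from .mmi import aicc

__all__ = [
    "ComponentSpec",
    "MixedModelComponent",
    "SemFit",
    "COMPONENT_SPECS",
    "fit_component",
    "select_random_effects",
    "fit_sem",
    "residual_correlation",
    "standardize_coefficients",
    "iq_effect",
]


@dataclass
class ComponentSpec:
    """Declarative description of one SEM component."""

    name: str
    response: str
    family: str                                  # "gaussian" | "binomial"
    candidates: list[str]                        # subject to all-subsets selection
    controls: list[str] = field(default_factory=list)  # always included
    re_candidates: tuple[tuple[str, ...], ...] = ((), ("block_id",), ("year",), ("block_id", "year"))
    correlated_error_partner: str | None = None


COMPONENT_SPECS: dict[str, ComponentSpec] = {
    "fertility": ComponentSpec(
        name="fertility",
        response="fertility_binary",
        family="binomial",
        candidates=["body_mass_kg", "arable_pct", "roe_density", "muntjac_density", "sqrt_fallow"],
        controls=["week_class"],
    ),
    "body_mass": ComponentSpec(
        name="body_mass",
        response="body_mass_kg",
        family="gaussian",
        candidates=["arable_pct", "roe_density", "muntjac_density", "sqrt_fallow"],
        controls=["week"],
    ),
    "roe_density": ComponentSpec(
        name="roe_density",
        response="roe_density",
        family="gaussian",
        candidates=["arable_pct", "sqrt_fallow"],
        correlated_error_partner="muntjac_density",
    ),
    "muntjac_density": ComponentSpec(
        name="muntjac_density",
        response="muntjac_density",
        family="gaussian",
        candidates=["arable_pct", "sqrt_fallow"],
        correlated_error_partner="roe_density",
    ),
}


class MixedModelComponent(BaseEstimator):
    """sklearn-style wrapper around one mixed-effects regression.

    Parameters mirror :func:`deersem.mixedmodels.fit_mixed_model`; after
    ``fit`` the result is available as ``result_`` plus convenience
    attributes ``coef_``, ``loglik_``, ``aicc_``.
    """

    def __init__(self, response: str = "y", fixed: tuple = (), family: str = "gaussian",
                 random_effects: tuple = (), min_rows_per_param: int = 10):
        self.response = response
        self.fixed = fixed
        self.family = family
        self.random_effects = random_effects
        self.min_rows_per_param = min_rows_per_param

    def fit(self, X: pd.DataFrame, y=None) -> "MixedModelComponent":
        self.result_ = fit_mixed_model(
            X, self.response, list(self.fixed), self.family,
            list(self.random_effects), self.min_rows_per_param,
        )
        self.coef_ = self.result_.params
        self.feature_names_in_ = np.asarray(self.result_.fixed_names)
        self.loglik_ = self.result_.loglik
        self.aicc_ = aicc(self.result_.loglik, self.result_.k, self.result_.n)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Population-level prediction (random effects at zero), response scale."""
        fit = self.result_
        cols = [np.ones(len(X))] + [np.asarray(X[c], dtype=float)
                                    for c in fit.fixed_names if c != "Intercept"]
        eta = np.column_stack(cols) @ fit.params
        if fit.family == "binomial":
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        return eta


@dataclass
class SemFit:
    """The assembled piecewise SEM at a single buffer radius."""

    radius_m: float
    components: dict[str, MixedModelFit]
    residual_correlation: float

    def r2_table(self) -> pd.DataFrame:
        rows = [
            {
                "component": name,
                "r2_marginal": f.r2_marginal,
                "r2_conditional": f.r2_conditional,
                "n": f.n,
                "loglik": f.loglik,
                "k": f.k,
            }
            for name, f in self.components.items()
        ]
        return pd.DataFrame(rows)


def fit_component(
    spec: ComponentSpec,
    subset: list[str],
    data: pd.DataFrame,
    random_effects: list[str] | None = None,
    min_rows_per_param: int = 10,
    theta_start=None,
) -> MixedModelFit:
    """Fit one component with the given candidate subset (controls always in)."""
    unknown = set(subset) - set(spec.candidates)
    if unknown:
        raise ValueError(f"{sorted(unknown)} not in candidate set for {spec.name}")
    fixed = list(spec.controls) + [c for c in spec.candidates if c in subset]
    return fit_mixed_model(
        data, spec.response, fixed, spec.family,
        random_effects, min_rows_per_param, theta_start,
    )


def select_random_effects(
    spec: ComponentSpec,
    data: pd.DataFrame,
    candidates: tuple[tuple[str, ...], ...] | None = None,
    min_rows_per_param: int = 10,
) -> tuple[str, ...]:
    """Choose the AICc-minimal random-intercept structure for the component,
    using the full fixed-effect model; ties break toward fewer parameters."""
    cands = list(candidates if candidates is not None else spec.re_candidates)
    if len(cands) == 1:
        return tuple(cands[0])
    results = []
    errors = []
    for re_struct in cands:
        try:
            fit = fit_component(spec, spec.candidates, data, list(re_struct),
                                min_rows_per_param)
        except FitError as e:
            errors.append((re_struct, str(e)))
            continue
        results.append((aicc(fit.loglik, fit.k, fit.n), len(re_struct), re_struct))
    if not results:
        raise FitError(
            f"no random-effect structure converged for {spec.name}: {errors}"
        )
    # sort by AICc then parameter count (fewer first) for tie-breaking
    results.sort(key=lambda t: (round(t[0], 9), t[1]))
    return tuple(results[0][2])


def residual_correlation(fit_a: MixedModelFit, fit_b: MixedModelFit) -> float:
    """Pearson correlation of the two components' response residuals.

    Reported as the SEM's correlated-error term; never interpreted as a
    directed path.
    """
    ra, rb = np.asarray(fit_a.resid), np.asarray(fit_b.resid)
    if ra.shape != rb.shape:
        raise ValueError("components were not fitted on the same row set")
    if np.std(ra) == 0 or np.std(rb) == 0:
        raise ValueError("zero-variance residuals: correlation undefined")
    return float(np.corrcoef(ra, rb)[0, 1])


def standardize_coefficients(fit: MixedModelFit, data: pd.DataFrame) -> dict[str, float]:
    """Coefficients rescaled by predictor and response standard deviations.

    beta* = beta * SD(x) / SD(y); for the binomial-logit family SD(y) is the
    latent-scale SD sqrt(var_fixed + var_RE + pi^2/3).
    """
    if fit.family == "gaussian":
        sd_y = float(np.std(data[fit.response].dropna(), ddof=1))
    else:
        sd_y = fit.latent_sd
    out = {}
    for name in fit.fixed_names:
        if name == "Intercept":
            continue
        sd_x = float(np.std(data[name].dropna(), ddof=1))
        if sd_x == 0:
            raise ValueError(f"zero-variance predictor {name!r}: cannot standardize")
        out[name] = fit.coef(name) * sd_x / sd_y
    return out


def iq_effect(fit: MixedModelFit, predictor: str, data: pd.DataFrame) -> float:
    """Interquartile effect on the response scale.

    Prediction at the predictor's third quartile minus prediction at its
    first quartile, all other covariates at their means and random effects
    at zero.  Gaussian components return response units; binomial components
    return the change in P(two embryos) in percentage points.
    """
    if predictor not in fit.fixed_names:
        raise KeyError(f"predictor {predictor!r} not in fitted component")
    q1, q3 = np.nanpercentile(np.asarray(data[predictor], dtype=float), [25, 75])
    base = {}
    for name in fit.fixed_names:
        if name == "Intercept":
            continue
        base[name] = float(np.nanmean(np.asarray(data[name], dtype=float)))

    def predict_at(value):
        eta = 0.0
        for name, b in zip(fit.fixed_names, fit.params):
            if name == "Intercept":
                eta += b
            elif name == predictor:
                eta += b * value
            else:
                eta += b * base[name]
        return eta

    e1, e3 = predict_at(q1), predict_at(q3)
    if fit.family == "binomial":
        p1 = 1.0 / (1.0 + np.exp(-e1))
        p3 = 1.0 / (1.0 + np.exp(-e3))
        return float((p3 - p1) * 100.0)
    return float(e3 - e1)


def fit_sem(
    data: pd.DataFrame,
    radius_m: float,
    re_structures: dict[str, tuple[str, ...]] | None = None,
    specs: dict[str, ComponentSpec] | None = None,
    min_rows_per_param: int = 10,
) -> SemFit:
    """Fit all components (full candidate sets) at one radius.

    ``data`` must be the feature-table rows for that radius.  The fertility
    component automatically drops rows without a fertility response (culls
    outside the embryo-detectability window).
    """
    specs = specs or COMPONENT_SPECS
    re_structures = re_structures or {}
    fits: dict[str, MixedModelFit] = {}
    for name, spec in specs.items():
        d = data
        if spec.response == "fertility_binary":
            d = data.dropna(subset=["fertility_binary"])
        re_struct = re_structures.get(name)
        if re_struct is None:
            re_struct = select_random_effects(spec, d, min_rows_per_param=min_rows_per_param)
        fits[name] = fit_component(spec, spec.candidates, d, list(re_struct),
                                   min_rows_per_param)
    rc = np.nan
    if "roe_density" in fits and "muntjac_density" in fits:
        rc = residual_correlation(fits["roe_density"], fits["muntjac_density"])
    return SemFit(radius_m=radius_m, components=fits, residual_correlation=rc)
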