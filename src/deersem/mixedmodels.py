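"""Mixed-effects regression components with crossed random intercepts.

Two families are supported, matching the regressions that make up the
piecewise structural equation model:

* gaussian (identity link): maximum likelihood, with the residual variance
  and fixed effects profiled out so the optimiser only searches over the
  variance ratios of the random intercepts.  All n x n covariance algebra is
  reduced to q x q systems (q = total number of random-effect levels) via
  the Woodbury identity, so fits are fast at any sample size.
* binomial (logit link): Laplace-approximate maximum likelihood.  For each
  candidate variance vector the joint penalised likelihood in (beta, u) is
  maximised by penalised IRLS, and the Laplace correction uses the log
  determinant of the penalised information of u.

Random effects are intercept-only and may be crossed (e.g. forest block and
cull year).  A variance that collapses to ~0 keeps its parameter slot so
information criteria stay comparable across candidate fixed structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = ["MixedModelFit", "FitError", "fit_mixed_model"]

_LOG2PI = np.log(2.0 * np.pi)


class FitError(RuntimeError):
    """Raised on non-convergence or separation; carries the model formula."""


@dataclass
class MixedModelFit:
    """Container for one fitted regression component."""

    family: str
    response: str
    fixed_names: list[str]            # includes "Intercept"
    params: np.ndarray                # link-scale coefficients
    bse: np.ndarray
    cov_params: np.ndarray
    loglik: float
    k: int                            # fixed + RE variances (+1 resid for gaussian)
    n: int
    re_names: list[str] = field(default_factory=list)
    re_var: dict[str, float] = field(default_factory=dict)
    sigma2: float | None = None       # gaussian residual variance
    theta: np.ndarray | None = None   # optimiser's variance parameters (log scale)
    var_fixed: float = 0.0            # variance of the linear predictor (fixed part)
    fitted: np.ndarray | None = None  # conditional fitted values (response scale)
    resid: np.ndarray | None = None   # conditional response residuals
    ranef: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def formula(self) -> str:
        fx = " + ".join(n for n in self.fixed_names if n != "Intercept") or "1"
        re = "".join(f" + (1|{g})" for g in self.re_names)
        return f"{self.response} ~ {fx}{re}"

    def coef(self, name: str) -> float:
        return float(self.params[self.fixed_names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.fixed_names.index(name)])

    # -- variance partition (Nakagawa-style) --------------------------------
    @property
    def _resid_var(self) -> float:
        if self.family == "gaussian":
            return float(self.sigma2)
        return np.pi**2 / 3.0  # latent logistic residual variance

    @property
    def total_re_var(self) -> float:
        return float(sum(self.re_var.values()))

    @property
    def r2_marginal(self) -> float:
        denom = self.var_fixed + self.total_re_var + self._resid_var
        return float(self.var_fixed / denom) if denom > 0 else 0.0

    @property
    def r2_conditional(self) -> float:
        denom = self.var_fixed + self.total_re_var + self._resid_var
        return float((self.var_fixed + self.total_re_var) / denom) if denom > 0 else 0.0

    @property
    def latent_sd(self) -> float:
        """SD of the response on the model's latent scale.

        For the binomial-logit family this is sqrt(var_fixed + var_RE +
        pi^2/3), the denominator used when standardising coefficients.
        """
        return float(np.sqrt(self.var_fixed + self.total_re_var + np.pi**2 / 3.0))


def _design(data: pd.DataFrame, response: str, fixed: list[str]):
    y = np.asarray(data[response], dtype=float)
    cols = [np.ones(len(data))]
    names = ["Intercept"]
    for t in fixed:
        x = np.asarray(data[t], dtype=float)
        if not np.all(np.isfinite(x)):
            raise FitError(f"non-finite values in predictor {t!r}")
        cols.append(x)
        names.append(t)
    X = np.column_stack(cols)
    return y, X, names


def _re_matrices(data: pd.DataFrame, groups: list[str]):
    """Indicator matrix Z (n x q) and per-factor column slices.

    Factors with fewer than 2 levels are dropped with a warning: a single
    level is indistinguishable from the intercept.
    """
    Zs, kept, sizes = [], [], []
    for g in groups:
        codes, levels = pd.factorize(data[g], sort=True)
        if len(levels) < 2:
            warnings.warn(f"random effect {g!r} has <2 levels; dropped", stacklevel=3)
            continue
        Zg = np.zeros((len(data), len(levels)))
        Zg[np.arange(len(data)), codes] = 1.0
        Zs.append(Zg)
        kept.append(g)
        sizes.append(len(levels))
    if not Zs:
        return None, [], []
    return np.hstack(Zs), kept, sizes


# ---------------------------------------------------------------------------
# gaussian: profiled ML
# ---------------------------------------------------------------------------

def _gaussian_profile(log_lam, stats, sizes, want_extras=True):
    """Profiled negative log likelihood at variance ratios exp(log_lam).

    V = sigma2 * (I + Z Lambda Z'); Lambda block-diagonal with one ratio per
    factor.  Everything is expressed through the precomputed cross-products
    in ``stats`` (X'X, X'y, Z'X, Z'y, Z'Z, y'y, n), so each evaluation costs
    O(q^3 + p^3) regardless of the sample size -- the Woodbury identity
    turns (I + Z Lam Z')^{-1} into a q x q solve.

    Returns (nll, beta, XtViX_inv, sigma2, u_hat).
    """
    XtX, Xty, ZtX, Zty, ZtZ, yty, n = stats
    lam = np.repeat(np.exp(log_lam), sizes)
    Lh = np.sqrt(lam)
    M = np.eye(len(lam)) + (Lh[:, None] * ZtZ) * Lh[None, :]
    cf = cho_factor(M, lower=True, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))

    LZtX = Lh[:, None] * ZtX          # q x p
    LZty = Lh * Zty                   # q
    B = np.column_stack([LZtX, LZty])
    MiB = cho_solve(cf, B, check_finite=False)
    MiLZtX, MiLZty = MiB[:, :-1], MiB[:, -1]
    XtViX = XtX - LZtX.T @ MiLZtX
    XtViy = Xty - LZtX.T @ MiLZty
    beta = np.linalg.solve(XtViX, XtViy)
    # r' V^-1 r = y'V^-1 y - 2 beta'X'V^-1 y + beta'X'V^-1 X beta
    ytViy = yty - LZty @ MiLZty
    qform = float(ytViy - 2.0 * beta @ XtViy + beta @ (XtViX @ beta))
    sigma2 = max(qform / n, 1e-12)
    nll = 0.5 * (n * _LOG2PI + n * np.log(sigma2) + logdet + n)
    if not want_extras:
        return nll, beta, None, sigma2, None
    # BLUPs: u = Lam (Z'r - Z'Z Lh M^-1 Lh Z'r) with Z'r = Zty - ZtX beta
    Ztr = Zty - ZtX @ beta
    LZtr = Lh * Ztr
    u_hat = Lh * (LZtr - (Lh[:, None] * ZtZ * Lh[None, :])
                  @ cho_solve(cf, LZtr, check_finite=False))
    return nll, beta, np.linalg.inv(XtViX), sigma2, u_hat


def _fit_gaussian(y, X, names, Z, groups, sizes, response, theta_start=None):
    n, p = X.shape
    if Z is None:
        # ordinary least squares, ML variance
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        sigma2 = max(float(r @ r) / n, 1e-12)
        ll = -0.5 * n * (_LOG2PI + np.log(sigma2) + 1.0)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        eta = X @ beta
        return MixedModelFit(
            family="gaussian", response=response, fixed_names=names,
            params=beta, bse=np.sqrt(np.diag(cov)), cov_params=cov,
            loglik=float(ll), k=p + 1, n=n, sigma2=sigma2,
            var_fixed=float(np.var(eta)), fitted=eta, resid=r,
        )

    nf = len(groups)
    stats = (X.T @ X, X.T @ y, Z.T @ X, Z.T @ y, Z.T @ Z, float(y @ y), n)
    obj = lambda t: _gaussian_profile(t, stats, sizes, want_extras=False)[0]
    if nf == 1:
        # one variance ratio: bounded Brent needs far fewer evaluations
        res = optimize.minimize_scalar(lambda t: obj(np.array([t])),
                                       bounds=(-20.0, 12.0), method="bounded",
                                       options={"xatol": 1e-6})
        theta_hat, fun = np.array([res.x]), res.fun
    else:
        if theta_start is not None:
            starts = [np.asarray(theta_start, dtype=float)]
        else:
            starts = [np.full(nf, -1.0), np.full(nf, 1.0)]
        best = None
        for start in starts:
            opts = {"xatol": 1e-5, "fatol": 1e-9, "maxiter": 2000}
            if theta_start is not None:
                # warm start: begin from a tight simplex around the seed
                opts["initial_simplex"] = np.vstack(
                    [start, start + 0.25 * np.eye(nf)])
            res = optimize.minimize(obj, start, method="Nelder-Mead",
                                    options=opts)
            if best is None or res.fun < best.fun:
                best = res
        theta_hat, fun = best.x, best.fun
    if not np.isfinite(fun):
        raise FitError(f"gaussian LMM failed to converge: {response}")
    nll, beta, XtViX_inv, sigma2, u_hat = _gaussian_profile(theta_hat, stats, sizes)
    cov = sigma2 * XtViX_inv
    re_var = {g: float(np.exp(t) * sigma2) for g, t in zip(groups, theta_hat)}
    eta = X @ beta
    # conditional fitted values: add BLUPs (u_hat already includes Lambda)
    fitted = eta + Z @ u_hat
    fit = MixedModelFit(
        family="gaussian", response=response, fixed_names=names,
        params=beta, bse=np.sqrt(np.diag(cov)), cov_params=cov,
        loglik=float(-nll), k=p + nf + 1, n=n,
        re_names=groups, re_var=re_var, sigma2=sigma2, theta=theta_hat,
        var_fixed=float(np.var(eta)), fitted=fitted, resid=y - fitted,
    )
    off = 0
    for g, s in zip(groups, sizes):
        fit.ranef[g] = pd.Series(u_hat[off:off + s])
        off += s
    return fit


# ---------------------------------------------------------------------------
# binomial: Laplace approximation
# ---------------------------------------------------------------------------

def _pirls(y, C, Pdiag, max_iter=200, tol=1e-9):
    """Penalised IRLS for logistic regression on design C with ridge-type
    penalty diag(Pdiag) (zero for fixed effects, 1/sigma_g^2 for levels)."""
    delta = np.zeros(C.shape[1])
    ll_pen_old = -np.inf
    for _ in range(max_iter):
        eta = C @ delta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        A = (C * w[:, None]).T @ C + np.diag(Pdiag)
        b = (C * w[:, None]).T @ z
        try:
            delta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise FitError(f"singular system in penalised IRLS: {e}")
        step = delta_new - delta
        delta = delta_new
        ll_pen = _binom_ll(y, C @ delta) - 0.5 * float(delta @ (Pdiag * delta))
        if abs(ll_pen - ll_pen_old) < tol and np.max(np.abs(step)) < 1e-6:
            break
        ll_pen_old = ll_pen
    if np.max(np.abs(delta)) > 1e3:
        raise FitError("separation suspected: unbounded coefficients")
    return delta, A


def _binom_ll(y, eta):
    eta = np.clip(eta, -30, 30)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def _laplace_nll(log_sig, y, X, Z, sizes):
    p = X.shape[1]
    sig2 = np.repeat(np.exp(2.0 * np.asarray(log_sig)), sizes)
    C = np.hstack([X, Z])
    Pdiag = np.concatenate([np.zeros(p), 1.0 / np.maximum(sig2, 1e-10)])
    delta, A = _pirls(y, C, Pdiag)
    beta, u = delta[:p], delta[p:]
    ll = _binom_ll(y, C @ delta)
    pen = 0.5 * float(u @ (u / np.maximum(sig2, 1e-10)))
    # Laplace correction: -0.5 log det(Z'WZ + D^-1) - 0.5 log det(D)
    Auu = A[p:, p:]
    sign, logdet_A = np.linalg.slogdet(Auu)
    if sign <= 0:
        return np.inf, None, None
    logdet_D = float(np.sum(np.log(np.maximum(sig2, 1e-10))))
    lap = ll - pen - 0.5 * (logdet_A + logdet_D)
    return -lap, delta, A


def _fit_binomial(y, X, names, Z, groups, sizes, response, theta_start=None):
    n, p = X.shape
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise FitError(f"binomial response {response!r} must be 0/1")
    if Z is None:
        delta, A = _pirls(y, X, np.zeros(p))
        ll = _binom_ll(y, X @ delta)
        cov = np.linalg.inv(A)
        eta = X @ delta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        return MixedModelFit(
            family="binomial", response=response, fixed_names=names,
            params=delta, bse=np.sqrt(np.diag(cov)), cov_params=cov,
            loglik=ll, k=p, n=n, var_fixed=float(np.var(eta)),
            fitted=mu, resid=y - mu,
        )

    nf = len(groups)
    obj = lambda t: _laplace_nll(t, y, X, Z, sizes)[0]
    if theta_start is not None:
        starts = [np.asarray(theta_start, dtype=float)]
    else:
        starts = [np.full(nf, -0.5), np.full(nf, 0.5)]
    best = None
    for start in starts:
        res = optimize.minimize(obj, start, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 1000})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise FitError(f"binomial GLMM failed to converge: {response}")
    nll, delta, A = _laplace_nll(best.x, y, X, Z, sizes)
    beta, u = delta[:p], delta[p:]
    cov_full = np.linalg.inv(A)
    cov = cov_full[:p, :p]
    re_var = {g: float(np.exp(2.0 * t)) for g, t in zip(groups, best.x)}
    eta_fix = X @ beta
    eta = eta_fix + Z @ u
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    fit = MixedModelFit(
        family="binomial", response=response, fixed_names=names,
        params=beta, bse=np.sqrt(np.diag(cov)), cov_params=cov,
        loglik=float(-nll), k=p + nf, n=n,
        re_names=groups, re_var=re_var, theta=best.x,
        var_fixed=float(np.var(eta_fix)), fitted=mu, resid=y - mu,
    )
    off = 0
    for g, s in zip(groups, sizes):
        fit.ranef[g] = pd.Series(u[off:off + s])
        off += s
    return fit


def fit_mixed_model(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    family: str = "gaussian",
    random_effects: list[str] | None = None,
    min_rows_per_param: int = 10,
    theta_start=None,
) -> MixedModelFit:
    """Fit one regression component by (approximate) maximum likelihood.

    Parameters
    ----------
    data : DataFrame with all referenced columns; rows with NaN in any used
        column are dropped.
    response : response column (0/1 for binomial).
    fixed : fixed-effect columns; an intercept is always added.
    family : "gaussian" or "binomial" (logit link).
    random_effects : grouping columns for crossed random intercepts.
    min_rows_per_param : guard against overfitting; set 0 to disable.
    """
    if family not in {"gaussian", "binomial"}:
        raise ValueError(f"unknown family {family!r}")
    random_effects = list(random_effects or [])
    used = [response] + list(fixed) + random_effects
    d = data.dropna(subset=used)
    y, X, names = _design(d, response, list(fixed))
    n, p = X.shape
    if min_rows_per_param and n < min_rows_per_param * p:
        raise FitError(
            f"{n} rows for {p} fixed parameters in {response} ~ {fixed}; "
            f"need >= {min_rows_per_param} rows per parameter"
        )
    Z, groups, sizes = _re_matrices(d, random_effects)
    if theta_start is not None and Z is not None and len(theta_start) != len(groups):
        theta_start = None
    if family == "gaussian":
        return _fit_gaussian(y, X, names, Z, groups, sizes, response, theta_start)
    return _fit_binomial(y, X, names, Z, groups, sizes, response, theta_start)
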