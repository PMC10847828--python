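"""Deterministic female-only Leslie matrix model.

Used to verify that senescent females (aged >= 8 years) are a negligible
fraction of the pre-birthing winter population, so that ignoring senescent
fertility decline in the individual-level analyses is defensible.

The census is pre-breeding: age classes 1..max_age are counted just before
the birth pulse, so recruitment into age class 1 folds neonatal survival
(birth to the following census) into the first matrix row:

    F_a = m_a * s_neonatal            (female offspring per female of age a)
    P_1 = s_yearling,  P_a = s_adult  (a >= 2, sub-diagonal)

The terminal class can be an absorbing plus-group (Usher form, default) or
truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LeslieParams",
    "LeslieModel",
    "build_leslie",
    "stable_age_distribution",
    "proportion_senescent",
    "DEFAULT_PARAMS",
]


@dataclass
class LeslieParams:
    """Vital rates for the female-only projection.

    fecundity_* are female offspring per female per year (embryo counts
    halved for an even sex ratio); survival_* are annual probabilities.
    survival_neonatal covers birth to the first pre-breeding census.
    """

    max_age: int = 12
    fecundity_yearling: float = 0.3
    fecundity_adult: float = 0.72
    survival_neonatal: float = 0.55
    survival_yearling: float = 0.75
    survival_adult: float = 0.70
    plus_group: bool = True

    def validate(self) -> None:
        if self.max_age < 9:
            raise ValueError("max_age must be >= 9 so that the >=8 y class is non-degenerate")
        for name in ("survival_neonatal", "survival_yearling", "survival_adult"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("fecundity_yearling", "fecundity_adult"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# Placeholder defaults for a heavily culled population; the study-site vital
# rates live outside this package, so these are illustrative only.
DEFAULT_PARAMS = LeslieParams()


class LeslieModel:
    """An assembled age-structured projection matrix.

    Parameters
    ----------
    fecundities : array of length n_ages
        First-row recruitment terms (already including neonatal survival).
    survivals : array of length n_ages - 1
        Sub-diagonal annual survival probabilities.
    plus_group : bool
        If True, the terminal class is absorbing with the last survival.
    ages : array of length n_ages, optional
        Age labels; defaults to 1..n_ages.
    """

    def __init__(self, fecundities, survivals, plus_group: bool = False, ages=None):
        f = np.asarray(fecundities, dtype=float)
        p = np.asarray(survivals, dtype=float)
        if f.ndim != 1 or p.ndim != 1 or p.size != f.size - 1:
            raise ValueError("need n fecundities and n-1 survivals")
        if np.any(f < 0):
            raise ValueError("fecundities must be non-negative")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        n = f.size
        A = np.zeros((n, n))
        A[0, :] = f
        A[np.arange(1, n), np.arange(n - 1)] = p
        if plus_group:
            A[n - 1, n - 1] = p[-1] if p.size else 0.0
        self.matrix = A
        self.ages = np.arange(1, n + 1) if ages is None else np.asarray(ages)

    @classmethod
    def from_rates(cls, params: LeslieParams) -> "LeslieModel":
        params.validate()
        n = params.max_age
        m = np.full(n, params.fecundity_adult)
        m[0] = params.fecundity_yearling
        f = m * params.survival_neonatal
        p = np.full(n - 1, params.survival_adult)
        p[0] = params.survival_yearling
        return cls(f, p, plus_group=params.plus_group)

    @property
    def growth_rate(self) -> float:
        """Dominant eigenvalue (asymptotic annual multiplication rate)."""
        return float(np.max(np.real(np.linalg.eigvals(self.matrix))))

    def stable_age_distribution(self) -> np.ndarray:
        """Normalised dominant right eigenvector (proportions summing to 1).

        Computed by power iteration on the damped matrix A + I, which has
        the same eigenvectors as A but is aperiodic, so the iteration
        converges even for cyclic age structures; the result is verified
        directly against the eigenvector equation A v = lambda v.
        """
        B = self.matrix + np.eye(self.matrix.shape[0])
        v = np.ones(self.matrix.shape[0])
        for _ in range(1000):
            v_new = B @ v
            s = v_new.sum()
            if s == 0:
                break
            v_new /= s
            if np.max(np.abs(v_new - v)) < 1e-14:
                v = v_new
                break
            v = v_new
        lam = self.growth_rate
        resid = np.max(np.abs(self.matrix @ v - lam * v))
        if resid > 1e-8 * max(1.0, lam):
            raise RuntimeError(
                f"power iteration did not reach the dominant eigenvector "
                f"(residual {resid:.3g}); matrix may be reducible"
            )
        return v

    def proportion_senescent(self, threshold_age: int = 8) -> float:
        dist = self.stable_age_distribution()
        return proportion_senescent(dist, self.ages, threshold_age)


def build_leslie(params: LeslieParams | None = None) -> LeslieModel:
    """Assemble the pre-breeding-census projection matrix from vital rates."""
    return LeslieModel.from_rates(params or DEFAULT_PARAMS)


def stable_age_distribution(model: LeslieModel) -> np.ndarray:
    return model.stable_age_distribution()


def proportion_senescent(distribution, ages, threshold_age: int = 8) -> float:
    """Summed stable-age proportion at or above ``threshold_age`` years."""
    dist = np.asarray(distribution, dtype=float)
    ages = np.asarray(ages)
    if not np.isclose(dist.sum(), 1.0):
        raise ValueError("distribution must be normalised")
    return float(dist[ages >= threshold_age].sum())
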