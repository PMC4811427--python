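"""State algebra of the illness-death model (IDM).

The IDM is the three-state compartment model Healthy -> Ill -> Dead with
transition rates ``i(t, a)`` (incidence), ``m0(t, a)`` (mortality of the
healthy) and ``m1(t, a)`` (mortality of the ill); ``t`` is calendar time and
``a`` is age, both in years, all rates per person-year.  Disease duration is
not modelled: ``m1`` depends on (t, a) only.

Writing ``p(t, a)`` for the age-specific prevalence (the ill fraction of the
alive population), the compartment ODEs along a birth cohort imply the
transport equation

    (d/dt + d/da) p = (1 - p) * (i - p * (m1 - m0)),

whose mortality term can equivalently be expressed through quantities that are
actually observable in practice — the general (all-cause, whole-population)
mortality ``m = p*m1 + (1-p)*m0`` and the mortality rate ratio ``R = m1/m0``:

    (d/dt + d/da) p = (1 - p) * (i - m * PAR(p, R)),

where ``PAR(p, R) = p(R-1) / (p(R-1) + 1)`` is the population attributable
risk, the proportion of deaths attributable to the disease.  Both right-hand
sides are exactly equal whenever (m, R) are derived from (p, m0, m1); the
module exposes both because downstream code receives mortality in one or the
other parametrisation.

All functions broadcast over numpy arrays and validate their domains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "RateModel",
    "MortalityInput",
    "par",
    "general_mortality",
    "pde_rhs_excess",
    "pde_rhs_par",
]

RateFunction = Callable[[np.ndarray, np.ndarray], np.ndarray]


def _as_checked_prob(p, name: str = "p"):
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError(f"{name} must be finite")
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError(f"{name} must lie in [0, 1]; got values outside")
    return p


def _as_finite(x, name: str):
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    return x


def _maybe_scalar(x: np.ndarray):
    return float(x) if np.ndim(x) == 0 else x


def par(p, R):
    """Population attributable risk ``p(R-1) / (p(R-1) + 1)``.

    The proportion of deaths in the whole population attributable to the
    disease, given prevalence ``p`` and mortality rate ratio ``R = m1/m0``.
    Lies in [0, 1) for R >= 1 and is negative for R < 1 (protective state).
    """
    p = _as_checked_prob(p)
    R = _as_finite(R, "R")
    if np.any(R <= 0.0):
        raise ValueError("relative mortality R must be > 0")
    denom = p * (R - 1.0) + 1.0
    if np.any(denom <= 0.0):
        raise ValueError(f"PAR denominator p*(R-1)+1 <= 0 for p={p!r}, R={R!r}")
    return _maybe_scalar(p * (R - 1.0) / denom)


def general_mortality(p, m0, m1):
    """All-cause mortality of the mixed population, ``m = p*m1 + (1-p)*m0``."""
    p = _as_checked_prob(p)
    m0 = _as_finite(m0, "m0")
    m1 = _as_finite(m1, "m1")
    return _maybe_scalar(p * m1 + (1.0 - p) * m0)


def pde_rhs_excess(p, i, m0, m1):
    """Rate of change of prevalence along a cohort line, excess-mortality form.

    Returns ``(1-p) * (i - p*(m1-m0))``, i.e. ``(1-p)*i - p*(1-p)*(m1-m0)``.
    The mortality term vanishes at p=0 (nobody ill) and p=1 (nobody healthy
    left to dilute the prevalence), as the compartment derivation requires.
    """
    p = _as_checked_prob(p)
    i = _as_finite(i, "i")
    m0 = _as_finite(m0, "m0")
    m1 = _as_finite(m1, "m1")
    return _maybe_scalar((1.0 - p) * (i - p * (m1 - m0)))


def pde_rhs_par(p, i, m, R):
    """Rate of change of prevalence along a cohort line, PAR form.

    Returns ``(1-p) * (i - m * PAR(p, R))``.  Numerically identical to
    :func:`pde_rhs_excess` when ``m = p*m1 + (1-p)*m0`` and ``R = m1/m0``:
    in that case ``m * PAR(p, R) = p * (m1 - m0)`` exactly.
    """
    p = _as_checked_prob(p)
    i = _as_finite(i, "i")
    m = _as_finite(m, "m")
    return _maybe_scalar((1.0 - p) * (i - m * par(p, R)))


@dataclass(frozen=True)
class RateModel:
    """The three rate surfaces of the IDM as vectorised callables of (t, a).

    Parameters
    ----------
    incidence, mortality_healthy, mortality_ill
        Functions ``(time, age) -> rate`` (per person-year), accepting numpy
        arrays and broadcasting.
    reference_time
        Calendar year at which the model's baseline curves are anchored.
    """

    incidence: RateFunction
    mortality_healthy: RateFunction
    mortality_ill: RateFunction
    reference_time: float

    def check(self, times, ages, warn_relative: bool = True) -> None:
        """Validate nonnegativity/finiteness of the rates on a (t, a) sample.

        Emits a warning (not an error) where ``m1 < m0``: a rate ratio below
        one is mathematically admissible but epidemiologically unusual for a
        chronic disease.
        """
        tt, aa = np.meshgrid(np.asarray(times, dtype=float), np.asarray(ages, dtype=float), indexing="ij")
        for name, fn in (
            ("incidence", self.incidence),
            ("mortality_healthy", self.mortality_healthy),
            ("mortality_ill", self.mortality_ill),
        ):
            vals = np.asarray(fn(tt, aa), dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"RateModel.{name} is non-finite on the requested (t, a) domain")
            if np.any(vals < 0.0):
                raise ValueError(f"RateModel.{name} is negative on the requested (t, a) domain")
        if warn_relative:
            m0 = np.asarray(self.mortality_healthy(tt, aa), dtype=float)
            m1 = np.asarray(self.mortality_ill(tt, aa), dtype=float)
            if np.any(m1 < m0):
                warnings.warn(
                    "mortality_ill < mortality_healthy somewhere on the grid (R < 1 is "
                    "epidemiologically unusual for a chronic disease)",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class MortalityInput:
    """Observed mortality at one estimation time: general mortality and rate ratio.

    ``m`` is the all-cause mortality of the whole population and ``R = m1/m0``
    the mortality rate ratio of ill vs healthy, both age-specific at calendar
    time ``time``.  These are the two quantities a practitioner can realistically
    obtain (vital statistics for ``m``; case-control studies for ``R``).
    """

    time: float
    ages: np.ndarray
    m: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        m = np.asarray(self.m, dtype=float)
        R = np.asarray(self.R, dtype=float)
        if ages.ndim != 1 or m.shape != ages.shape or R.shape != ages.shape:
            raise ValueError("ages, m, R must be 1-d arrays of equal length")
        if len(ages) == 0:
            raise ValueError("MortalityInput needs at least one age")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(R))):
            raise ValueError("m and R must be finite")
        if np.any(m < 0):
            raise ValueError("general mortality m must be >= 0")
        if np.any(R <= 0):
            raise ValueError("relative mortality R must be > 0")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "R", R)

    def at_ages(self, ages) -> tuple[np.ndarray, np.ndarray]:
        """Return (m, R) at the requested ages; exact node match required."""
        ages = np.asarray(ages, dtype=float)
        idx = np.searchsorted(self.ages, ages)
        idx = np.clip(idx, 0, len(self.ages) - 1)
        # searchsorted may land one to the right of the closest node
        left = np.clip(idx - 1, 0, len(self.ages) - 1)
        use_left = np.abs(self.ages[left] - ages) < np.abs(self.ages[idx] - ages)
        idx = np.where(use_left, left, idx)
        if np.any(np.abs(self.ages[idx] - ages) > 1e-9):
            bad = ages[np.abs(self.ages[idx] - ages) > 1e-9]
            raise ValueError(f"mortality input at t={self.time} does not cover age(s) {bad[:5].tolist()}")
        return self.m[idx], self.R[idx]
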