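"""Incidence estimators from pairs of prevalence cross-sections.

Two estimators recover the age-specific incidence ``i(t*, a)`` at a time
``t*`` strictly between two surveys at ``t1 < t2``, given the general
mortality ``m`` and the mortality rate ratio ``R`` at ``t*``:

* **direct** — inverts the IDM transport equation:
  ``i = (d/dt + d/da)p / (1 - p) + m * PAR(p, R)``, with the characteristic
  (cohort-line) derivative approximated by a centered difference between the
  two surveys and ``p(t*, a)`` by linear interpolation along the cohort line.

* **least squares** — propagates a guessed incidence from ``t*`` to both
  survey times by a first-order characteristic step and minimises the
  sigma-weighted squared deviation from the observed prevalences, subject to
  ``i >= 0``.  Each age enters exactly two residual cells, so the problem
  decouples into per-age scalar minimisations solved in closed form.

Estimates live on the *half-offset* grid: with yearly surveys at integer ages
the estimation ages are 30.5, 31.5, ..., so that the cohort line through
``(t*, a)`` lands exactly on observed nodes ``(t1, a - h1)`` and
``(t2, a + h2)``.  No age interpolation is ever performed.

On noise-free data with equal sigmas, the closed-form least-squares solution
is algebraically identical to the direct estimator (under the default
characteristic-consistent propagation convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from previnc.idm_model import MortalityInput, par, pde_rhs_par

__all__ = [
    "CrossSection",
    "IncidenceEstimate",
    "SingularPrevalenceError",
    "midpoint_prevalence",
    "characteristic_derivative",
    "direct_incidence",
    "predict_cross_sections",
    "chi_square",
    "ls_incidence",
    "estimate_series",
    "trend_fit",
]

logger = logging.getLogger(__name__)

Convention = Literal["characteristic", "literal"]

_AGE_TOL = 1e-9


class SingularPrevalenceError(ValueError):
    """Raised when the interpolated prevalence is too close to 1 (division by 1-p)."""


@dataclass(frozen=True)
class CrossSection:
    """One survey: age-specific prevalence at a fixed calendar time.

    ``sigma`` (standard error of each prevalence) and ``n`` (sample size) are
    optional; absent sigma means a complete survey / noise-free input.
    """

    time: float
    ages: np.ndarray
    p: np.ndarray
    sigma: Optional[np.ndarray] = None
    n: Optional[np.ndarray] = None

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if ages.ndim != 1 or p.shape != ages.shape:
            raise ValueError("ages and p must be 1-d arrays of equal length")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p >= 1):
            bad = np.where(~((p >= 0) & (p < 1)))[0]
            raise ValueError(
                f"prevalence must lie in [0, 1); offending age(s) "
                f"{ages[bad][:5].tolist()} at t={self.time}"
            )
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "p", p)
        for name in ("sigma", "n"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != ages.shape:
                    raise ValueError(f"{name} must match ages in length")
                if np.any(val < 0) or np.any(~np.isfinite(val)):
                    raise ValueError(f"{name} must be finite and >= 0")
                object.__setattr__(self, name, val)

    def value_at(self, age: float) -> float:
        return float(self.p[self._index(age)])

    def _index(self, age: float) -> int:
        idx = int(np.argmin(np.abs(self.ages - age)))
        if abs(self.ages[idx] - age) > _AGE_TOL:
            raise ValueError(f"age node {age} not present in cross-section at t={self.time}")
        return idx

    def _indices(self, ages: np.ndarray) -> np.ndarray:
        out = np.empty(len(ages), dtype=int)
        for k, a in enumerate(np.asarray(ages, dtype=float)):
            out[k] = self._index(a)
        return out


@dataclass(frozen=True)
class IncidenceEstimate:
    """Estimated age-specific incidence at one mid-survey time.

    ``clamped`` flags ages where a negative raw estimate was truncated at 0
    (the nonnegativity constraint was active).
    """

    time: float
    ages: np.ndarray
    incidence: np.ndarray
    method: str
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None
    clamped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        inc = np.asarray(self.incidence, dtype=float)
        if inc.shape != ages.shape:
            raise ValueError("incidence must match ages in length")
        if np.any(inc < 0):
            raise ValueError("incidence estimates must be >= 0")
        clamped = self.clamped
        if clamped is None:
            clamped = np.zeros(ages.shape, dtype=bool)
        clamped = np.asarray(clamped, dtype=bool)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "incidence", inc)
        object.__setattr__(self, "clamped", clamped)
        for name in ("lower", "upper"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, np.asarray(val, dtype=float))
        if self.lower is not None and np.any(self.lower - inc > 1e-12):
            raise ValueError("lower bounds must not exceed the point estimate")
        if self.upper is not None and np.any(inc - self.upper > 1e-12):
            raise ValueError("upper bounds must not fall below the point estimate")

    def value_at(self, age: float) -> float:
        idx = int(np.argmin(np.abs(self.ages - age)))
        if abs(self.ages[idx] - age) > _AGE_TOL:
            raise ValueError(f"age {age} not on the estimate's age grid")
        return float(self.incidence[idx])


def _offsets(cs1: CrossSection, cs2: CrossSection, t_star: float) -> tuple[float, float]:
    if not (cs1.time < t_star < cs2.time):
        raise ValueError(f"need t1 < t* < t2; got t1={cs1.time}, t*={t_star}, t2={cs2.time}")
    return t_star - cs1.time, cs2.time - t_star


def estimation_ages(cs1: CrossSection, cs2: CrossSection, t_star: float) -> np.ndarray:
    """Ages a for which both cohort-line nodes (t1, a-h1) and (t2, a+h2) exist."""
    h1, h2 = _offsets(cs1, cs2, t_star)
    cand = cs1.ages + h1
    other = cs2.ages - h2
    # exact intersection up to tolerance
    sel = []
    for a in cand:
        if np.any(np.abs(other - a) < _AGE_TOL):
            sel.append(a)
    if not sel:
        raise ValueError("no common cohort-line age nodes between the two cross-sections")
    return np.asarray(sel, dtype=float)


def midpoint_prevalence(cs1: CrossSection, cs2: CrossSection, t_star: float, age: float) -> float:
    """Prevalence at (t*, age) by linear interpolation along the cohort line.

    ``p(t*, a) ~= h2/(h1+h2) * p(t1, a-h1) + h1/(h1+h2) * p(t2, a+h2)``.
    The two age arguments must be exact nodes of the respective surveys.
    """
    h1, h2 = _offsets(cs1, cs2, t_star)
    p1 = cs1.value_at(age - h1)
    p2 = cs2.value_at(age + h2)
    return (h2 * p1 + h1 * p2) / (h1 + h2)


def characteristic_derivative(cs1: CrossSection, cs2: CrossSection, t_star: float, age: float) -> float:
    """Centered difference of prevalence along the cohort line through (t*, age).

    ``[p(t2, a+h2) - p(t1, a-h1)] / (h1 + h2)`` — second-order accurate for the
    directional derivative (d/dt + d/da)p at the midpoint.
    """
    h1, h2 = _offsets(cs1, cs2, t_star)
    return (cs2.value_at(age + h2) - cs1.value_at(age - h1)) / (h1 + h2)


def _vector_inputs(cs1: CrossSection, cs2: CrossSection, mort: MortalityInput):
    """Aligned per-age arrays shared by both estimators."""
    t_star = mort.time
    h1, h2 = _offsets(cs1, cs2, t_star)
    ages = estimation_ages(cs1, cs2, t_star)
    i1 = cs1._indices(ages - h1)
    i2 = cs2._indices(ages + h2)
    p1 = cs1.p[i1]
    p2 = cs2.p[i2]
    p_star = (h2 * p1 + h1 * p2) / (h1 + h2)
    m, R = mort.at_ages(ages)
    s1 = cs1.sigma[i1] if cs1.sigma is not None else np.ones_like(p1)
    s2 = cs2.sigma[i2] if cs2.sigma is not None else np.ones_like(p2)
    return t_star, h1, h2, ages, p1, p2, p_star, m, R, s1, s2


def _check_singularity(p_star: np.ndarray, ages: np.ndarray, eps: float) -> None:
    if np.any(p_star >= 1.0 - eps):
        bad = ages[p_star >= 1.0 - eps]
        raise SingularPrevalenceError(
            f"interpolated prevalence within {eps} of 1 at age(s) {bad[:5].tolist()}; "
            "the direct inversion divides by 1 - p"
        )


def direct_incidence(
    cs1: CrossSection,
    cs2: CrossSection,
    mort: MortalityInput,
    eps: float = 1e-9,
) -> IncidenceEstimate:
    """Direct inversion of the transport equation at t* = ``mort.time``.

    Per half-offset age: ``i = dchar/(1 - p*) + m * PAR(p*, R)`` with ``p*``
    the cohort-line midpoint prevalence and ``dchar`` the centered difference.
    Raw negative values are truncated at 0 and flagged.
    """
    t_star, h1, h2, ages, p1, p2, p_star, m, R, _, _ = _vector_inputs(cs1, cs2, mort)
    _check_singularity(p_star, ages, eps)
    dchar = (p2 - p1) / (h1 + h2)
    raw = dchar / (1.0 - p_star) + m * par(p_star, R)
    clamped = raw < 0.0
    if np.any(clamped):
        logger.info(
            "direct estimate at t*=%.6g: %d negative value(s) truncated at 0", t_star, int(clamped.sum())
        )
    return IncidenceEstimate(
        time=t_star, ages=ages, incidence=np.maximum(raw, 0.0), method="direct", clamped=clamped
    )


def predict_cross_sections(
    p_star: np.ndarray,
    i_guess: np.ndarray,
    mort: MortalityInput,
    h1: float,
    h2: float,
    convention: Convention = "characteristic",
):
    """First-order characteristic propagation of a guessed incidence to t1 and t2.

    ``p_star`` and ``i_guess`` are defined on ``mort.ages`` (the half-offset
    estimation grid).  Returns ``(ages1, p1_pred, ages2, p2_pred)``: each
    estimation age ``a`` predicts the observed cells ``(t2, a + h2)`` and —
    under the default characteristic convention — ``(t1, a - h1)``.  The
    alternative ``literal`` convention predicts ``(t1, a + h1)`` instead
    (the flattened-text reading of the backward step; kept as a switch).

    Predictions escaping [0, 1] are clipped with a logged warning.
    """
    p_star = np.asarray(p_star, dtype=float)
    i_guess = np.asarray(i_guess, dtype=float)
    ages = mort.ages
    if p_star.shape != ages.shape or i_guess.shape != ages.shape:
        raise ValueError("p_star and i_guess must be defined on mort.ages")
    if np.any(i_guess < 0):
        raise ValueError("i_guess must be >= 0")
    rhs = pde_rhs_par(p_star, i_guess, mort.m, mort.R)
    p2_pred = p_star + h2 * rhs
    ages2 = ages + h2
    if convention == "characteristic":
        p1_pred = p_star - h1 * rhs
        ages1 = ages - h1
    elif convention == "literal":
        p1_pred = p_star - h1 * rhs
        ages1 = ages + h1
    else:
        raise ValueError(f"unknown convention {convention!r}")
    for name, arr in (("t1", p1_pred), ("t2", p2_pred)):
        out = (arr < 0.0) | (arr > 1.0)
        if np.any(out):
            logger.warning("%d propagated prevalence value(s) at %s clipped to [0, 1]", int(out.sum()), name)
            np.clip(arr, 0.0, 1.0, out=arr)
    return ages1, p1_pred, ages2, p2_pred


def chi_square(
    i_guess: np.ndarray,
    cs1: CrossSection,
    cs2: CrossSection,
    mort: MortalityInput,
    convention: Convention = "characteristic",
) -> float:
    """Sigma-weighted sum of squared deviations between observed and propagated
    prevalences over the cells reachable from the estimation grid.

    Unset sigmas count as 1 (plain least squares).
    """
    t_star, h1, h2, ages, p1, p2, p_star, m, R, s1, s2 = _vector_inputs(cs1, cs2, mort)
    mort_sub = MortalityInput(time=t_star, ages=ages, m=m, R=R)
    ages1, p1_pred, ages2, p2_pred = predict_cross_sections(
        p_star, np.asarray(i_guess, dtype=float), mort_sub, h1, h2, convention
    )
    obs1 = cs1.p[cs1._indices(ages1)]
    obs2 = cs2.p[cs2._indices(ages2)]
    sig1 = cs1.sigma[cs1._indices(ages1)] if cs1.sigma is not None else np.ones_like(obs1)
    sig2 = cs2.sigma[cs2._indices(ages2)] if cs2.sigma is not None else np.ones_like(obs2)
    r1 = obs1 - p1_pred
    r2 = obs2 - p2_pred
    for r, s in ((r1, sig1), (r2, sig2)):
        if np.any((s == 0) & (np.abs(r) > 0)):
            raise ValueError("sigma = 0 with a nonzero residual: infinite weight")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms1 = np.where((sig1 == 0), 0.0, (r1 / np.where(sig1 == 0, 1.0, sig1)) ** 2)
        terms2 = np.where((sig2 == 0), 0.0, (r2 / np.where(sig2 == 0, 1.0, sig2)) ** 2)
    return float(terms1.sum() + terms2.sum())


def ls_incidence(
    cs1: CrossSection,
    cs2: CrossSection,
    mort: MortalityInput,
    eps: float = 1e-9,
    convention: Convention = "characteristic",
) -> IncidenceEstimate:
    """Weighted nonnegative least-squares incidence estimate at t* = ``mort.time``.

    The propagated prevalences are linear in each age's incidence guess, and
    each guess enters exactly two residual cells, so the minimiser has the
    closed form of a weighted scalar regression, projected onto [0, inf).
    """
    t_star, h1, h2, ages, p1, p2, p_star, m, R, s1, s2 = _vector_inputs(cs1, cs2, mort)
    _check_singularity(p_star, ages, eps)
    if np.any(s1 == 0) or np.any(s2 == 0):
        raise ValueError("sigma = 0 not allowed in the least-squares weighting")
    mpar = m * par(p_star, R)
    one_minus = 1.0 - p_star
    # predicted cells as linear functions alpha + beta * i of the per-age guess
    beta2 = h2 * one_minus
    alpha2 = p_star - beta2 * mpar
    beta1 = -h1 * one_minus
    alpha1 = p_star - beta1 * mpar
    if convention == "characteristic":
        obs1 = p1  # cell (t1, a - h1)
        sig1 = s1
    else:  # literal: cell (t1, a + h1)
        idx1 = cs1._indices(ages + h1)
        obs1 = cs1.p[idx1]
        sig1 = cs1.sigma[idx1] if cs1.sigma is not None else np.ones_like(obs1)
    w1 = 1.0 / sig1**2
    w2 = 1.0 / s2**2
    num = w1 * beta1 * (obs1 - alpha1) + w2 * beta2 * (p2 - alpha2)
    den = w1 * beta1**2 + w2 * beta2**2
    raw = num / den
    clamped = raw < 0.0
    if np.any(clamped):
        logger.info(
            "least-squares estimate at t*=%.6g: %d negative value(s) truncated at 0",
            t_star,
            int(clamped.sum()),
        )
    return IncidenceEstimate(
        time=t_star, ages=ages, incidence=np.maximum(raw, 0.0), method="least_squares", clamped=clamped
    )


_METHODS = {"direct": direct_incidence, "least_squares": ls_incidence, "ls": ls_incidence}


def estimate_series(
    cross_sections: Sequence[CrossSection],
    mortality: Sequence[MortalityInput],
    method: str = "direct",
    **kwargs,
) -> list[IncidenceEstimate]:
    """Apply an estimator to every consecutive pair of a survey series.

    ``n`` cross-sections yield ``n - 1`` estimates at the pairs' midpoint
    times; one :class:`MortalityInput` must be supplied per pair, timed at the
    pair's midpoint.  Input order is irrelevant (sorted internally).
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    if len(cross_sections) < 2:
        raise ValueError("need at least two cross-sections")
    cs = sorted(cross_sections, key=lambda c: c.time)
    mort_by_time = {round(m.time, 9): m for m in mortality}
    estimates = []
    for c1, c2 in zip(cs[:-1], cs[1:]):
        t_star = round((c1.time + c2.time) / 2.0, 9)
        if t_star not in mort_by_time:
            raise ValueError(
                f"no mortality input at the midpoint t*={t_star} of surveys "
                f"{c1.time} and {c2.time}; available: {sorted(mort_by_time)}"
            )
        estimates.append(_METHODS[method](c1, c2, mort_by_time[t_star], **kwargs))
    return estimates


def trend_fit(estimates: Sequence[IncidenceEstimate], age: float) -> float:
    """Annual percentage change of incidence at one age across a series.

    Ordinary least squares of log(incidence) on estimation time; returns
    ``100 * (exp(slope) - 1)``, i.e. the fitted multiplicative change per year
    expressed in percent.
    """
    if len(estimates) < 3:
        raise ValueError("need at least three estimates for a trend fit")
    times = np.array([e.time for e in estimates], dtype=float)
    vals = np.array([e.value_at(age) for e in estimates], dtype=float)
    if np.any(vals <= 0):
        raise ValueError(
            f"incidence at age {age} is zero/clamped in at least one estimate; "
            "pick an age with strictly positive estimates"
        )
    order = np.argsort(times)
    slope = np.polyfit(times[order], np.log(vals[order]), 1)[0]
    return float(100.0 * np.expm1(slope))
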