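"""Sampling-noise model for survey prevalence and bootstrap confidence bands.

Real surveys report prevalence per age group with binomial sampling error
``sigma^2 = p (1 - p) / n``.  The noise model resamples each group's count
``~ Binomial(n, p)`` and uses the resampled proportion — the unique mean-zero
additive perturbation of ``p`` with exactly that variance whose result can
never leave [0, 1].

Uncertainty in the incidence estimate is quantified by a parametric bootstrap:
superimpose fresh binomial noise B times (default B = 2000), re-estimate each
time, and take per-age empirical percentiles (2.5 / 50 / 97.5, linear
interpolation as in ``numpy.percentile``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from previnc.estimators import CrossSection, SingularPrevalenceError, direct_incidence, ls_incidence
from previnc.idm_model import MortalityInput

__all__ = [
    "NoiseSpec",
    "BootstrapResult",
    "binomial_sigma",
    "add_binomial_noise",
    "bootstrap_incidence",
    "default_age_groups",
]

logger = logging.getLogger(__name__)

#: Stand-in per-group sample sizes for the survey scenario: 5-year groups from
#: 30-34 upward with decreasing n at higher ages (the last group is 95-100 so
#: the oldest survey age used by the estimators is covered).
DEFAULT_GROUP_SIZES = (2000, 2000, 1500, 1500, 1000, 1000, 750, 750, 500, 500, 250, 250, 100, 100)


def default_age_groups() -> list[tuple[float, float]]:
    """5-year age groups 30-34, 35-39, ..., 90-94 plus 95-100."""
    groups = [(30.0 + 5 * k, 34.0 + 5 * k) for k in range(13)]
    groups.append((95.0, 100.0))
    return groups


@dataclass(frozen=True)
class NoiseSpec:
    """Grouped binomial sampling design: closed age intervals and per-group n."""

    age_groups: Sequence[tuple[float, float]] = field(default_factory=default_age_groups)
    n: Sequence[int] = DEFAULT_GROUP_SIZES
    seed: Optional[int] = None

    def __post_init__(self):
        groups = [(float(lo), float(hi)) for lo, hi in self.age_groups]
        if len(groups) != len(self.n):
            raise ValueError("one sample size per age group required")
        if any(ni < 1 for ni in self.n):
            raise ValueError("sample sizes must be >= 1")
        for (lo, hi) in groups:
            if hi < lo:
                raise ValueError(f"malformed age group ({lo}, {hi})")
        for (lo1, hi1), (lo2, hi2) in zip(groups[:-1], groups[1:]):
            if lo2 <= hi1 and lo1 <= hi2:
                raise ValueError(f"overlapping age groups ({lo1}, {hi1}) and ({lo2}, {hi2})")
        object.__setattr__(self, "age_groups", groups)
        object.__setattr__(self, "n", tuple(int(ni) for ni in self.n))

    def group_of(self, age: float) -> int:
        for k, (lo, hi) in enumerate(self.age_groups):
            if lo - 1e-9 <= age <= hi + 1e-9:
                return k
        raise ValueError(f"age {age} is not covered by any noise age group")


def binomial_sigma(p, n):
    """Standard error of a binomial proportion, ``sqrt(p (1 - p) / n)``."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    out = np.sqrt(p * (1.0 - p) / n)
    return float(out) if out.ndim == 0 else out


def add_binomial_noise(cs: CrossSection, spec: NoiseSpec, rng: np.random.Generator) -> CrossSection:
    """Superimpose grouped binomial sampling noise on a cross-section.

    Per group: the prevalence at the group's representative age (the interval
    midpoint, snapped to the nearest member age on the survey grid) is
    resampled as ``Binomial(n, p)/n``; the noisy value, its binomial standard
    error, and ``n`` are broadcast to all member ages.
    """
    group_idx = np.array([spec.group_of(a) for a in cs.ages], dtype=int)
    p_noisy = np.empty_like(cs.p)
    sigma = np.empty_like(cs.p)
    n_out = np.empty_like(cs.p)
    for k, (lo, hi) in enumerate(spec.age_groups):
        members = np.where(group_idx == k)[0]
        if len(members) == 0:
            continue
        mid = 0.5 * (lo + hi)
        rep = members[np.argmin(np.abs(cs.ages[members] - mid))]
        p_rep = cs.p[rep]
        n_k = spec.n[k]
        draw = rng.binomial(n_k, p_rep) / n_k
        p_noisy[members] = draw
        sigma[members] = binomial_sigma(p_rep, n_k)
        n_out[members] = n_k
    return CrossSection(time=cs.time, ages=cs.ages.copy(), p=p_noisy, sigma=sigma, n=n_out)


@dataclass(frozen=True)
class BootstrapResult:
    """Per-age median and 95% percentile band over B bootstrap estimates."""

    t_star: float
    ages: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    B: int
    n_excluded: int = 0

    def __post_init__(self):
        for name in ("ages", "median", "lower", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.median.shape == self.lower.shape == self.upper.shape == self.ages.shape):
            raise ValueError("ages, median, lower, upper must have equal shapes")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if np.any(self.lower - self.median > 1e-12) or np.any(self.median - self.upper > 1e-12):
            raise ValueError("need lower <= median <= upper per age")

    def covers(self, truth: np.ndarray) -> np.ndarray:
        """Boolean per age: does [lower, upper] contain the given truth?"""
        truth = np.asarray(truth, dtype=float)
        return (self.lower <= truth) & (truth <= self.upper)


def bootstrap_incidence(
    cs1: CrossSection,
    cs2: CrossSection,
    mort: MortalityInput,
    spec: NoiseSpec,
    B: int = 2000,
    method: str = "direct",
    rng: Optional[np.random.Generator] = None,
) -> BootstrapResult:
    """Percentile bootstrap of the incidence estimate under binomial noise.

    Each of the B replicates superimposes independent grouped binomial noise on
    both cross-sections and re-runs the estimator.  Replicates on which the
    estimator hits the p -> 1 singularity are excluded and counted in
    ``n_excluded``.  All randomness flows from ``rng`` (or ``spec.seed``).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    estimator = {"direct": direct_incidence, "least_squares": ls_incidence, "ls": ls_incidence}[method]
    draws = []
    ages = None
    n_excluded = 0
    for _ in range(B):
        noisy1 = add_binomial_noise(cs1, spec, rng)
        noisy2 = add_binomial_noise(cs2, spec, rng)
        try:
            est = estimator(noisy1, noisy2, mort)
        except SingularPrevalenceError:
            n_excluded += 1
            continue
        ages = est.ages
        draws.append(est.incidence)
    if not draws:
        raise RuntimeError("all bootstrap replicates failed the p -> 1 singularity guard")
    if n_excluded:
        logger.warning("bootstrap: %d of %d replicate(s) excluded (singular prevalence)", n_excluded, B)
    stack = np.vstack(draws)
    lower, median, upper = np.percentile(stack, [2.5, 50.0, 97.5], axis=0)
    return BootstrapResult(
        t_star=mort.time,
        ages=ages,
        median=median,
        lower=lower,
        upper=upper,
        B=B,
        n_excluded=n_excluded,
    )
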