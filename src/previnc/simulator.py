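"""Forward simulation of prevalence surfaces by integration along characteristics.

The prevalence transport PDE ``(d/dt + d/da) p = (1-p)(i - p(m1-m0))`` reduces
to an ordinary differential equation along cohort lines ``t - a = const`` (the
characteristics).  Each cohort is integrated with the classical 4th-order
Runge-Kutta scheme using a substep that divides the grid step evenly, so every
grid node is hit exactly and no interpolation is ever performed.

Cohorts alive at the first grid time start from the supplied initial age
profile ``p0``; cohorts that reach the minimum age later start from a boundary
value, by default the time-constant ``p0(a_min)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from previnc.idm_model import RateModel, pde_rhs_excess

__all__ = [
    "AgeTimeGrid",
    "PrevalenceSurface",
    "PrevalenceBoundError",
    "simulate_prevalence",
    "cross_sections_from_surface",
]


class PrevalenceBoundError(RuntimeError):
    """Raised when an integrated prevalence leaves [0, 1)."""


def _uniform_step(axis: np.ndarray, name: str) -> float:
    d = np.diff(axis)
    if len(d) == 0:
        raise ValueError(f"{name} needs at least two points")
    if np.any(d <= 0):
        raise ValueError(f"{name} must be strictly increasing")
    step = float(d[0])
    if not np.allclose(d, step, rtol=0, atol=1e-9):
        raise ValueError(f"{name} must be uniformly spaced")
    return step


@dataclass(frozen=True)
class AgeTimeGrid:
    """Rectangular calendar-time x age grid with a shared step.

    The time step must equal the age step so that characteristics connect grid
    nodes; ``integration_substep`` must divide that step evenly.
    """

    times: np.ndarray
    ages: np.ndarray
    integration_substep: float = 0.1

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        ages = np.asarray(self.ages, dtype=float)
        tstep = _uniform_step(times, "times")
        astep = _uniform_step(ages, "ages")
        if abs(tstep - astep) > 1e-9:
            raise ValueError(
                f"time step ({tstep}) must equal age step ({astep}) so that "
                "characteristics pass through grid nodes"
            )
        if self.integration_substep <= 0:
            raise ValueError("integration_substep must be > 0")
        ratio = astep / self.integration_substep
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"integration_substep ({self.integration_substep}) must divide the grid step ({astep}) evenly"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ages", ages)

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def substeps_per_node(self) -> int:
        return round(self.step / self.integration_substep)

    @classmethod
    def regular(
        cls,
        t_start: float,
        t_end: float,
        age_min: float,
        age_max: float,
        step: float = 1.0,
        integration_substep: float = 0.1,
    ) -> "AgeTimeGrid":
        times = t_start + step * np.arange(round((t_end - t_start) / step) + 1)
        ages = age_min + step * np.arange(round((age_max - age_min) / step) + 1)
        return cls(times=times, ages=ages, integration_substep=integration_substep)


@dataclass(frozen=True)
class PrevalenceSurface:
    """Age-specific prevalence on an :class:`AgeTimeGrid` (shape: times x ages)."""

    grid: AgeTimeGrid
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.grid.times), len(self.grid.ages)):
            raise ValueError("values must have shape (n_times, n_ages)")
        if np.any(~np.isfinite(values)) or np.any(values < 0) or np.any(values >= 1):
            raise ValueError("prevalence values must lie in [0, 1)")
        object.__setattr__(self, "values", values)

    def time_index(self, time: float) -> int:
        idx = int(round((time - self.grid.times[0]) / self.grid.step))
        if idx < 0 or idx >= len(self.grid.times) or abs(self.grid.times[idx] - time) > 1e-9:
            raise ValueError(
                f"time {time} is not on the grid; available: {self.grid.times[0]}..{self.grid.times[-1]} "
                f"step {self.grid.step}"
            )
        return idx

    def age_indices(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        idx = np.round((ages - self.grid.ages[0]) / self.grid.step).astype(int)
        ok = (idx >= 0) & (idx < len(self.grid.ages))
        if not np.all(ok) or np.any(np.abs(self.grid.ages[np.clip(idx, 0, len(self.grid.ages) - 1)] - ages) > 1e-9):
            raise ValueError(f"age(s) not on the grid: {ages}")
        return idx

    def at(self, time: float, ages) -> np.ndarray:
        """Prevalence values at one grid time and a subset of grid ages."""
        return self.values[self.time_index(time), self.age_indices(ages)]

    def to_frame(self):
        """Long-format DataFrame with columns time, age, prevalence."""
        import pandas as pd

        tt, aa = np.meshgrid(self.grid.times, self.grid.ages, indexing="ij")
        return pd.DataFrame(
            {"time": tt.ravel(), "age": aa.ravel(), "prevalence": self.values.ravel()}
        )


def _rk4_step(f: Callable, t: float, p: np.ndarray, h: float) -> np.ndarray:
    k1 = f(t, p)
    k2 = f(t + 0.5 * h, p + 0.5 * h * k1)
    k3 = f(t + 0.5 * h, p + 0.5 * h * k2)
    k4 = f(t + h, p + h * k3)
    return p + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def simulate_prevalence(
    model: RateModel,
    initial_prevalence: np.ndarray,
    grid: AgeTimeGrid,
    boundary: Optional[Callable[[float], float]] = None,
    check_model: bool = True,
) -> PrevalenceSurface:
    """Integrate the IDM transport equation over the grid.

    Parameters
    ----------
    model
        The rate surfaces i, m0, m1.
    initial_prevalence
        ``p0`` on ``grid.ages`` at the first grid time.
    boundary
        Prevalence at the minimum age for cohorts entering after the first
        time, as a function of calendar time.  Default: the time-constant
        ``p0(a_min)``.  Estimates near the minimum age in late years inherit
        whatever assumption is made here.
    check_model
        Validate rate nonnegativity/finiteness on the grid first.

    Raises
    ------
    PrevalenceBoundError
        If any integrated prevalence leaves [0, 1); the offending (t, a) is
        reported.
    """
    p0 = np.asarray(initial_prevalence, dtype=float)
    if p0.shape != grid.ages.shape:
        raise ValueError("initial_prevalence must be defined on grid.ages")
    if np.any(p0 < 0) or np.any(p0 >= 1):
        raise ValueError("initial prevalence must lie in [0, 1)")
    if boundary is None:
        pa_min = float(p0[0])
        boundary = lambda t: pa_min  # noqa: E731  time-constant boundary
    if check_model:
        model.check(grid.times, grid.ages)

    t0 = float(grid.times[0])
    a_min, a_max = float(grid.ages[0]), float(grid.ages[-1])
    h = grid.integration_substep
    per_node = grid.substeps_per_node
    n_nodes = len(grid.times) - 1

    values = np.full((len(grid.times), len(grid.ages)), np.nan)
    values[0, :] = p0

    # Lock-step march over global time; each active cohort is identified by its
    # constant offset c = a - t, so its age at time t is t + c.
    offsets = grid.ages - t0
    p = p0.copy()

    def rhs(t: float, pv: np.ndarray) -> np.ndarray:
        a = t + offsets
        # clip transient RK stage values at the open upper bound; the accepted
        # step itself is bound-checked below
        pv = np.clip(pv, 0.0, 1.0)
        return pde_rhs_excess(pv, model.incidence(t, a), model.mortality_healthy(t, a), model.mortality_ill(t, a))

    age_lookup_tol = 1e-9
    for node in range(n_nodes):
        t_node = t0 + node * grid.step
        for sub in range(per_node):
            t = t_node + sub * h
            p = _rk4_step(rhs, t, p, h)
        t_next = t_node + grid.step
        ages_now = t_next + offsets
        if np.any(p < -1e-12) or np.any(p >= 1.0):
            bad = np.where((p < -1e-12) | (p >= 1.0))[0][0]
            raise PrevalenceBoundError(
                f"prevalence left [0, 1) at t={t_next:.6g}, a={ages_now[bad]:.6g} (p={p[bad]:.6g})"
            )
        p = np.maximum(p, 0.0)

        # drop cohorts beyond the oldest age; enter a new cohort at a_min
        keep = ages_now <= a_max + age_lookup_tol
        offsets = offsets[keep]
        ages_now = ages_now[keep]
        p = p[keep]
        b = float(boundary(t_next))
        if not (0.0 <= b < 1.0):
            raise ValueError(f"boundary prevalence at t={t_next} must lie in [0, 1); got {b}")
        offsets = np.concatenate(([a_min - t_next], offsets))
        ages_now = np.concatenate(([a_min], ages_now))
        p = np.concatenate(([b], p))

        on_grid = np.round((ages_now - a_min) / grid.step).astype(int)
        values[node + 1, on_grid] = p

    if np.any(np.isnan(values)):
        raise RuntimeError("internal error: unfilled grid nodes after integration")
    return PrevalenceSurface(grid=grid, values=values)


def cross_sections_from_surface(
    surface: PrevalenceSurface,
    times: Sequence[float],
    ages: Optional[Sequence[float]] = None,
):
    """Extract survey-like cross-sections (no sampling error) from a surface.

    ``ages``, if given, subsets the grid ages (e.g. integer survey ages from a
    half-year simulation grid); values are taken from the surface bit-for-bit.
    """
    from previnc.estimators import CrossSection

    if ages is None:
        ages_arr = surface.grid.ages
    else:
        ages_arr = np.asarray(ages, dtype=float)
    out = []
    for t in times:
        p = surface.at(float(t), ages_arr)
        out.append(CrossSection(time=float(t), ages=ages_arr.copy(), p=p.copy()))
    return out
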