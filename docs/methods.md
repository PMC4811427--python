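# Methods

## Model

The illness-death model (IDM) has three states — Healthy, Ill, Dead — and
three transition rates per person-year: incidence `i(t,a)`, mortality of the
healthy `m0(t,a)` and mortality of the ill `m1(t,a)`, all functions of
calendar time `t` and age `a` (years). Disease duration is not modelled:
`m1` is assumed independent of time since diagnosis. Migration is assumed
prevalence-neutral (migrants carry the resident prevalence).

Writing `S` and `C` for the healthy and ill counts, the cohort ODEs
`S' = −(i+m0)S`, `C' = iS − m1C` imply that the prevalence
`p = C/(S+C)` satisfies, along any cohort line `t − a = const`,

    (d/ds) p = (1−p)·(i − p·(m1−m0)).

The same equation in terms of the observable general mortality
`m = p·m1 + (1−p)·m0` and rate ratio `R = m1/m0` is

    (d/ds) p = (1−p)·(i − m·PAR(p,R)),   PAR(p,R) = p(R−1)/(p(R−1)+1),

and the two forms are *identical* (not merely approximately equal): since
`p(R−1)+1 = m/m0`, one has `m·PAR(p,R) = p·(m1−m0)` exactly. A property
test asserts the identity to 1e−12 relative on random inputs. The package
stores mortality as `(m, R)` rather than `(m0, m1)` in all estimation-facing
interfaces because rate ratios travel across populations better than rate
differences, and `m` is what vital statistics provide. `R < 1` (ill people
dying less) is admissible algebra but flagged with a warning.

## Forward simulation

`simulate_prevalence` integrates the transport equation with classical RK4
along characteristics. The grid couples the time and age axes with a common
step (default 1 year for survey-like output, 0.5 year inside the validation)
so that cohort lines connect grid nodes exactly; the integration substep
(default 0.1 year) must divide the grid step, so sampling onto the grid is by
exact landing — no interpolation anywhere. RK4 stage values are clipped to
[0, 1] (rate evaluation only); an accepted step leaving [0, 1) aborts the
simulation with the offending `(t, a)`.

Boundary handling: cohorts alive at the first time start from the supplied
initial profile `p0(a)`; cohorts reaching the minimum age later start from a
time-constant boundary `p(t, a_min) = p0(a_min)` (configurable). Estimates
near the minimum age in late years inherit this assumption.

The scheme's 4th-order convergence is verified against the closed form
`p = 1 − exp(−i·(a − a_min))` of the constant-rate, `m1 = m0` case (error
ratio ≥ 8 when halving the substep; equality to 1e−6 at the default substep).

## Estimators

Estimation works on the half-offset grid: with surveys at `t1 < t2` and
`t* = mort.time` in between (`h1 = t*−t1`, `h2 = t2−t*`), an estimate at age
`a` uses exactly the two observed nodes `(t1, a−h1)` and `(t2, a+h2)` on the
cohort line through `(t*, a)`. For yearly integer-age surveys this yields
ages 30.5, 31.5, …, 99.5. Exact node matching is enforced (tolerance 1e−9
years); missing nodes are an error naming the node.

**Direct estimator.** `i = Δp/(h1+h2)/(1−p*) + m·PAR(p*, R)` with
`Δp` the centered difference along the cohort line (second-order accurate at
the midpoint) and `p*` the convex combination
`h2/(h1+h2)·p(t1,a−h1) + h1/(h1+h2)·p(t2,a+h2)`. A guard rejects
`p* ≥ 1 − ε` (default ε = 1e−9). Negative raw estimates are truncated at 0
and flagged per age (`clamped`), never dropped silently.

**Least-squares estimator.** A guessed incidence is propagated from `t*` to
both survey times by one first-order characteristic step (the propagated
prevalences are linear in the guess), and the σ-weighted squared deviation
from the observed cells is minimised subject to `i ≥ 0`. Each age's guess
enters exactly two cells, so the problem decouples into per-age scalar
weighted regressions solved in closed form and projected onto [0, ∞); the
closed form is verified against a bounded numeric scalar search in tests.
Unset σ defaults to 1 (plain least squares). With no noise and equal σ the
closed form reduces algebraically to the direct estimator — the two methods'
error tables are identical, as the validation confirms at per-1e5 rounding.

*Backward-step convention.* The backward propagation to `t1` can be anchored
at `p*(a+h1)` (characteristic-consistent: the cell `(t1, a−h1)` lies on the
same cohort line as the estimate) or at `p*(a−h1)` (a literal reading of the
first-order step). The characteristic-consistent variant is the default —
it is the one under which noise-free least squares reproduces the direct
estimator — and the other is available via `convention="literal"`.

Series estimation applies an estimator to every consecutive survey pair
(`n` surveys → `n−1` estimates at midpoint times); mortality inputs must be
timed at the pairs' midpoints and are used as given — no temporal or age
interpolation of mortality is performed. The secular trend at one age is the
OLS slope of log-incidence on time, reported as `100·(exp(slope)−1)` %/yr.

## Sampling noise and bootstrap

Survey noise follows the binomial model `σ² = p(1−p)/n` per (survey, age
group). "Additive mean-zero binomial noise" is realised as the resampled
proportion `Binomial(n, p)/n` — the unique mean-zero perturbation with
exactly that variance that cannot leave [0, 1]. Groups are closed age
intervals; one draw per group, taken at the group's representative (midpoint)
age, is broadcast to all member ages, mirroring how grouped surveys report.
Per-age noise is the special case of 1-year groups. The shipped default
design uses 5-year groups from 30–34 upward with sizes
2000, 2000, 1500, 1500, 1000, 1000, 750, 750, 500, 500, 250, 250, 100, 100;
these are synthetic stand-ins for a realistic ageing survey, and the last
group spans 95–100 so the oldest survey age used by the estimators is
covered. All sizes and boundaries are configurable.

`bootstrap_incidence` superimposes fresh noise on both surveys B times
(default B = 2000), re-estimates, and reports per-age median and 2.5/97.5
empirical percentiles (numpy's linear-interpolation definition; no BCa).
Replicates hitting the `p → 1` guard are excluded and counted. All
randomness flows from one seeded generator; identical seed + configuration
reproduces results bitwise.

Two distinct things are checked about the bands. (1) Qualitatively, at
survey-scale sample sizes the 95 % band contains the generating incidence at
the large majority of ages and widens at high ages where samples are small.
(2) Calibration: with per-age noise and samples large enough that the
nonnegativity clamp stays inactive, the band's coverage of the truth over
200 simulated surveys (reduced B = 200) is statistically compatible with
95 %. Multi-year grouping is deliberately excluded from the calibration
check: broadcasting one value per group erases the age gradient along the
cohort line and biases the estimator by more than the sampling noise at
large n — a property of grouped surveys themselves, not of the bootstrap.

## Validation scenario

The built-in scenario emulates diabetes among Danish men aged 30+ over
1995–2004 at the level of aggregated rates. Rates are anchored at 2004 and
trended multiplicatively: `rate(y, a) = baseline(a) · factor^(y − 2004)` with
factors 1.053 (incidence), 0.975 (`m0`) and 0.961 (`m1`) applied uniformly
across ages — so the 2003 incidence is exactly 1/1.053 = 95.0 % of 2004, and
mortality is *higher* in earlier years.

The published register analysis reports the 2004 age curves only in
aggregate, so the baselines here are documented synthetic stand-ins chosen
for epidemiological plausibility and fixed once:

- incidence: logistic in age, `0.0012 + 0.014/(1+exp(−(a−63)/8))` — about
  1.6/1000/yr in the late thirties rising to a plateau near 15/1000/yr;
- `m0`: Gompertz, `0.02·exp(0.095·(a−70))`;
- `R(a) = 1.5 + 2.5·exp(−0.055·(a−30))`, declining from 4 at age 30 toward
  1.5 at high age; `m1 = R·m0`.

The 1995 initial prevalence is generated by a cohort warm-up: integrating
the transport ODE in age from `p(30) = 0` with calendar time frozen at 1995
(a cross-sectional stand-in for the unobserved pre-1995 history). The
simulation then runs on a half-year (t, a) grid so the half-offset
estimation nodes are exact grid nodes; the yearly integer-age cross-sections
serve as survey inputs, and the general mortality fed to the estimators is
computed exactly as `p·m1 + (1−p)·m0` from the simulated prevalence and the
generating rates at `t*` — the mortality inputs are treated as known, since
uncertainty in mortality data is outside this package's scope.

With these stand-ins the validation reproduces the expected structure: both
estimators give identical error tables at per-1e5 rounding, median/maximum
absolute relative errors decline monotonically from 1995.5 to 2003.5
(49→37 and 439→68 per 1e5), the overall maximum stays below 0.9 %, and the
log-linear trend fit at age 65.5 recovers 5.30 %/yr. Because the baseline
curves are stand-ins, cell-level error values are properties of this
configuration, not reproductions of any external table; only the structural
claims above are asserted. The whole loop runs in well under a minute on one
CPU (problem size: 9 estimation times × 70 ages, substep 0.1 year).

## What the synthetic scenario does and does not show

Passing validation demonstrates that the estimators invert the model that
generated the data, at realistic rate magnitudes and trends, under exact
mortality inputs and either no noise or binomial survey noise. It does not
exercise: errors or trends *in the mortality inputs*; migration with
prevalence differential; duration-dependent excess mortality; age-specific
trend factors (the scenario trends all ages uniformly); remission
(irreversibility is built into the model); or real survey artefacts
(non-response, measurement error beyond binomial sampling). Estimates near
the minimum age in late calendar years additionally depend on the boundary
assumption `p(t, a_min) = p0(a_min)`.

## Numerical defaults

| quantity | default | rationale |
| --- | --- | --- |
| RK4 substep | 0.1 yr | truncation error far below estimator discretisation error |
| singularity guard ε | 1e−9 | rejects `p* ≥ 1−ε` before the 1/(1−p) division |
| age node tolerance | 1e−9 yr | exact-match lookup with float-safe slack |
| bootstrap B | 2000 | percentile stability at the 2.5/97.5 tails |
| percentiles | linear interpolation | numpy default, documented for reproducibility |
| LS convention | characteristic | reproduces the direct estimator on noise-free data |
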