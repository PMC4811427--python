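# previnc

Estimate age-specific **incidence rates of chronic (irreversible) diseases —
and their secular trends — from a series of prevalence cross-sections plus
mortality data**, without a disease register and without follow-up studies.

Surveillance programmes often have repeated prevalence surveys and vital
statistics, but no affordable way to measure incidence directly. For a
chronic disease described by the illness-death model (Healthy → Ill → Dead,
with incidence `i(t,a)`, mortality of the healthy `m0(t,a)` and of the ill
`m1(t,a)`), the age-specific prevalence `p(t,a)` obeys the transport equation

    (∂t + ∂a) p = (1 − p) · [ i − p·(m1 − m0) ]
                = (1 − p) · [ i − m · PAR(p, R) ],

where `m = p·m1 + (1−p)·m0` is the general (all-cause) mortality,
`R = m1/m0` the mortality rate ratio, and
`PAR(p, R) = p(R−1)/(p(R−1)+1)` the population attributable risk. Solving
for `i` turns two consecutive prevalence surveys at `t1 < t2`, together with
`(m, R)` at an intermediate time `t*`, into an incidence estimate:

    i(t*, a) = [(∂t + ∂a) p] / (1 − p)  +  m · PAR(p, R)

with the cohort-line derivative approximated by a centered difference between
the two surveys and `p(t*, a)` by linear interpolation along the cohort line
(estimates land on the half-offset ages 30.5, 31.5, … for yearly surveys at
integer ages). A second estimator solves the same problem as a σ-weighted
nonnegative least-squares fit, which lets unequal survey sampling errors be
weighted; on noise-free equal-weight data the two estimators coincide.

The package provides:

- `idm_model` — the illness-death-model state algebra (both PDE forms, PAR,
  general mortality);
- `simulator` — forward simulation of prevalence surfaces by classical RK4
  integration along cohort characteristics;
- `estimators` — the direct and least-squares estimators, series estimation
  over many surveys, and log-linear trend fitting;
- `uncertainty` — grouped binomial survey noise (`σ² = p(1−p)/n`) and
  percentile-bootstrap confidence bands (default B = 2000);
- `danish_rates` — a self-contained validation scenario emulating diabetes
  among Danish men 1995–2004 (incidence growing 5.3 %/yr; mortalities of the
  healthy/ill declining 2.5 %/3.9 %/yr), used to verify the whole pipeline;
- `cli_io` — tidy-CSV formats, YAML configuration and the `previnc` command
  line (`simulate`, `estimate`, `bootstrap`, `validate`).

## Worked example

```python
from previnc import run_validation

result = run_validation(method="both")
print(f"trend at age 65.5 (direct): {result.trend_pct['direct']:.4f} %/yr")
for s in result.summaries["direct"]:
    print(f"  t*={s.t_star}: median {s.median_per1e5:5.1f}  max {s.max_per1e5:6.1f}  (per 1e5)")
```

prints

```
trend at age 65.5 (direct): 5.2997 %/yr
  t*=1995.5: median  48.6  max  439.3  (per 1e5)
  t*=1996.5: median  47.3  max  317.6  (per 1e5)
  t*=1997.5: median  45.1  max  234.8  (per 1e5)
  t*=1998.5: median  44.2  max  177.2  (per 1e5)
  t*=1999.5: median  42.2  max  136.3  (per 1e5)
  t*=2000.5: median  40.9  max  106.8  (per 1e5)
  t*=2001.5: median  39.4  max   85.3  (per 1e5)
  t*=2002.5: median  37.8  max   69.4  (per 1e5)
  t*=2003.5: median  37.0  max   67.9  (per 1e5)
```

Reading: the scenario's true incidence grows by 5.3 %/yr and the log-linear
fit to the nine estimated mid-year incidences at age 65.5 recovers
5.2997 %/yr. The table gives the median and maximum absolute relative error
of the estimated vs generating incidence over ages 30.5…99.5, in units of
1 per 100 000 — the worst cell anywhere is 439 per 1e5, i.e. all estimates
are within 0.44 % of truth, and the errors shrink as the surveys get closer
to the reference year of the rate trends. The least-squares column (not
shown) is identical at this rounding.

The same scenario from the shell:

```sh
previnc validate --method both --out validation.csv
```

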