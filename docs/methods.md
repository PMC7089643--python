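# Methods

## Model structure

Both models describe one consumer population and one resource in a
seasonal environment. Time runs in growing seasons of `Y = 250` days; the
"winter" between seasons is not simulated, on the assumption that all
rates are negligible then, so seasons are contiguous and the annual
reproduction pulse sits exactly at each season boundary `t_n = n Y`.

### Individual energetics

All consumer rates are mass-specific. Intake is Holling type II with
half-saturation `H`; assimilated intake (`sigma`) minus maintenance `T`
gives net production `nu`. The asymmetry parameter `q` weights juvenile
ingestion by `2 - q` and adult ingestion by `q`, so the total intake
capacity of the population is unchanged while its distribution over
stages shifts: `q < 1` favours juveniles, `q > 1` adults. When `nu < 0`
the shortfall is paid from structural biomass, book-kept as starvation
mortality `d = mu - nu`; growth, maturation and reproductive investment
all stop. Adults route positive production into an energy store that does
not forage, pays no maintenance, and perishes with its owner; stored
energy is irreversible (it cannot later cover maintenance).

`M`, `T` and `mu` scale as `0.1, 0.01, 0.0015 * W_A^(-1/4)` per day, so
the adult body size `W_A` places a species on a fast–slow continuum: a
0.02 g consumer lives ~250 days (one reproductive event), a 200 g
consumer ~2500 days (ten events).

### Cohort model (PSPM)

Each cohort carries `(c_i, s_i, g_i)`. Juveniles (`Sb <= s < Sm`) grow
exponentially at rate `nu_J^+`; adults (`s = Sm`) accumulate storage at
`nu_A^+ Sm` per capita. When the largest juvenile cohort reaches `Sm` a
maturation event relabels it as adult (identity map on `c, s, g`; the
resource is untouched). The annual pulse converts all storage into one
newborn cohort with `c_0 = sum(g_i c_i)/Sb`, conserving biomass exactly.

Implementation choices:

* **Event handling.** Within a season the ODEs are integrated segment by
  segment; a terminal root condition on `max(s_juvenile) - Sm` halts the
  solver, the cohort is relabelled with `s` pinned to exactly `Sm`
  (preventing drift), and integration resumes. If several cohorts sit at
  `Sm` simultaneously — possible after a season with no growth leaves
  cohorts with identical sizes — all of them are matured before resuming.
* **Cohort book-keeping.** Adults are never merged; cohort counts are
  bounded by culling cohorts whose biomass `c(s+g)` falls below 1e-12 of
  total consumer biomass (after each pulse). Removed biomass is logged in
  the pulse registry and stays below 1e-9 of the total per event in all
  presets.
* **Initial condition.** The default start is a resource at `Rmax` and a
  single newborn cohort of 0.1 mg/L introduced just after a nominal
  reproduction instant at `t = 0`; both are configurable.
* **Simultaneous events.** If a maturation root coincides with a season
  boundary, maturation is applied first; since a cohort maturing at that
  instant carries no storage, the order affects labelling only, not
  biomass.

### Stage-structured biomass model

Biomass per juvenile stage `J_1..J_n`, adults `A`, storage `B`, resource
`R` — `n + 3` ODEs. The cohort-level maturation event is replaced by the
per-capita rate `gamma(nu_J, d_J)` derived by requiring that the expected
lifetime biomass one newborn delivers to the adult stage at fixed
resource density, `Sm z^(mu_J/nu_J)`, is preserved. The rate is zero under
starvation, continuous everywhere, and has a removable singularity at
`nu = d` with limit `-d/ln(z)`.

With `n > 1` juvenile stages the juvenile size range is split evenly on a
log scale (`z_eff = z^(1/n)`); all stages are energetically equivalent
(same `nu_J`, `d_J` and `2 - q` foraging weight), each passes biomass to
the next at the same `gamma`, and newborn biomass enters `J_1` only. This
makes the maturation time of biomass Erlang/gamma-distributed with shape
`n`, and the per-stage contribution factors multiply to the same overall
limit for every `n` — so the expected adult contribution is independent
of the stage count, which the tests verify against an adaptive-quadrature
oracle.

## Numerical choices

* Integration uses `scipy.integrate.solve_ivp` with LSODA (Adams with
  automatic switch to BDF if a run stiffens), `rtol = 1e-8`,
  `atol = 1e-10`, dense output for trace sampling. State dimension is
  `3 * n_cohorts + 1` for the cohort model (a few hundred at most under
  the default culling) and `n + 3` for the stage model.
* The maturation rate switches to a 2nd-order series of
  `x / (1 - e^(xL/nu))` when `|nu - d| < 1e-7 max(nu, d)` (catastrophic
  cancellation), and evaluates the denominator in log space when
  `nu << d` so heavy starvation underflows to zero instead of
  overflowing.
* Traces sample on a fixed 1-day grid via dense output plus tagged
  pre/post rows at every pulse and maturation event; time averages use
  the trapezoid rule, which the duplicate-time event rows split at each
  discontinuity so jumps are never averaged across.
* Year boundaries are exact by construction (each season is integrated
  on `[nY, (n+1)Y]`); pulse maps are closed-form and conserve consumer
  biomass and resource to round-off.

## Experiment protocol

Long-run summaries follow a fixed protocol: integrate 200,000 days per
parameter value at full scale, average over the trailing 60 %, and sample
post-reproduction states over the last 10,000 days (40 years). The
package defaults to a desk-scale variant — 20,000 days per step with the
post-pulse window scaled proportionally — with the full-scale protocol one
flag away (`--paper-scale`). Bifurcation sweeps step the parameter in
small increments, warm-starting each run from the previous endpoint
(ascending by default; both directions are available for hysteresis
checks, and on fixed-point regimes they agree to ~1e-4). For adult-mass
sweeps of the cohort model the warm start rescales individual sizes by
`Sm_new/Sm_old` so every cohort keeps its relative position in the
size range. A "year without reproduction" is a pulse below 1e-6 of the
standing consumer biomass — the cutoff is a package choice; skip-year
pulses are structurally zero in the cohort model and many orders of
magnitude below normal pulses in the stage model, so the statistic is
insensitive to the exact value.

The test suite and the acceptance script run scaled-down versions of
these experiments: 100-year runs for the cross-model comparisons at
`W_A = 50` g and 800-year stage-model runs (the full-scale duration; the
stage model is cheap) for the reproduction-gap statistics at `W_A = 1` g,
discarding the first half as transient.

## What the simulations do and do not show

The presets emulate the study conditions — invertebrate-like consumers of
0.02–200 g on a semi-chemostat resource (`Rmax = 20` mg/L an order of
magnitude above `H = 3` mg/L, turnover 0.1/day, chosen for consumer
persistence) — not any particular empirical system. Agreement between the
two models here demonstrates the internal consistency of the
stage-structured approximation, not predictive validity for field data.
Known behaviours: with equal or adult-favoured competition (`q >= 1`)
both models converge to regular seasonal oscillations and their time
averages agree closely; with juvenile-favoured competition (`q < 1`) the
cohort model produces large-amplitude single-cohort cycles (including
skipped reproductive years) that the one-stage model smooths out, so
averages deviate — adding juvenile stages moves the stage model closer.

## Limitations

* One consumer species, one resource; no stage-specific diets, multiple
  adult stages, or within-winter mortality (the framework extends to
  these, but they are out of scope here).
* Storage is irreversible and maturation in the stage model is memoryless
  within a stage; real maturation-time spread lies between the two
  extremes the models bracket.
* Deterministic throughout: no demographic or environmental
  stochasticity, although such variation is known to break up the extreme
  single-cohort cycles of the cohort model.
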