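# Methods

## The estimand and the excess-incidence method

A screen-detected cancer is *overdiagnosed* within a horizon of `t` years
if, absent screening, it would not have been diagnosed in that window —
either because the host dies of other causes first or because its clinical
presentation lies beyond the horizon. With a stop-screen randomised trial
(one-off screen, long unscreened follow-up), the trial-wide quantity

```
E(t) = min{1, (F_A(t) − F_B(t)) / R_A}
```

estimates the fraction of screen-detected cancers not yet matched by a
compensatory deficit in the screened arm. `F_A`, `F_B` are *net* cumulative
incidences — Kaplan–Meier complements with death and loss treated as
independent censoring — so `E(t)` refers to a hypothetical world without
competing death. Early after the screen `E` is 100% by construction (no
screen-detected cancer could have presented yet); it falls as the
compensatory drop plays out, and only once the drop has closed does `E(T)`
estimate overdiagnosis net of mortality.

Two assumptions carry the method: net excess is independent of competing
mortality (reasonable for prostate cancer, which is not strongly linked to
other causes of death), and independent of age (weaker than assuming
incidence is age-independent). Under them, `E(t) = S1(t)` is treated as the
survival function of the counterfactual presentation time among
screen-detected cancers.

## Competing-risks projection

Annual excess hazards are `h1(k) = log S1(k−1) − log S1(k)` for years
`k = 1..T` since screening. Other-cause mortality enters as annual hazards
`h2(a)` per year of age from a cause-deleted life table (all-cause minus
prostate-cancer mortality; negative differences floored at zero with a
warning). Both hazards are constant within each one-year interval. Interval
survival over ages is `S2(b, c) = exp(−Σ_{a=b}^{c−1} h2(a))`, ages `b`
inclusive to `c` exclusive, so `S2(a, a+1)` covers exactly one year.

The probability that the cancer of a man screened at age `a` presents in
year `k` is the classical competing-risks interval term,

```
w_k = h1(k)/(h1(k)+h2(a+k−1)) · (1 − e^{−(h1(k)+h2(a+k−1))})
      · S1(k−1) · S2(a, a+k−1),
```

with `w_k := 0` when `h1(k) = 0` (the 0/0 plateau case), and projected
overdiagnosis is `O(a, t) = 1 − Σ_{k≤t} w_k`.

**Start-of-interval convention.** The interval term multiplies survival to
the *start* of interval `k`, `S1(k−1)·S2(a, a+k−1)`. This is the only
indexing under which (i) the sum telescopes exactly so that `O(a, t) =
S1(t)` when `h2 ≡ 0` — crude excess equals net excess when nobody dies —
and (ii) presentations + deaths + survivors sum to 1 exactly. Both are
enforced to 1e−12 in tests. An end-of-interval variant
(`S1(k)·S2(a, a+k)`) fails both limits and is not offered.

During the plateau years (`h1 = 0`) no presentation mass accrues, but the
intervals still deplete `S2`: deaths in years 1..t0 are precisely what
drives `O(a, t)` above `S1(t)`, and they dominate the age gradient.

## S1 constructions

Two constructions are available on the yearly grid `k = 0..T`:

* **linearized** (default, the headline specification): `S1 = 1` up to the
  plateau end `t0`, then a straight-line decline to `E(T)` with slope
  `(1 − E(T))/(T − t0)` per year. With `E(T) = 11.7%`, `T = 15`, `t0 = 3`
  the slope is 7.36% of screen-detected cases per year.
* **nonparametric**: `S1(k) = min(1, (F_A(k) − F_B(k))/R_A)` from the
  yearly-interpolated curves, repaired to non-increasing by a running
  minimum (warned when applied; conservative and order-preserving). Any
  non-positive value on the grid is rejected with instructions to use the
  linearized form, since `log S1` must exist.

Defaults `T = 15` years and `t0 = 3` years: the capped excess is 100% for
roughly the first three years of follow-up, i.e. essentially no
screen-detected cancer would have presented clinically within 3 years.
Both are configurable.

## Uncertainty

Published trial reports print per-arm incidences with 95% CIs rather than
microdata, so standard errors are recovered as CI width / (2·1.96) —
assuming symmetric normal intervals — and combined by the z-statistic:
`se_diff = √(se_A² + se_B²)`, bounds `(diff ± 1.96·se_diff)/R_A`, the lower
bound floored at 0 (overdiagnosis is a proportion of screen-detected
cases) and the upper capped at 100%. The Kaplan–Meier estimator
accordingly reports plain normal CIs on `F` from Greenwood variances by
default (so that width-recovery inverts them exactly); log-log bands are
available behind a flag. Bootstrap and cluster-robust intervals are out of
scope.

The contamination scenario rescales the excess for control-arm testing:
`E · uptake/(uptake − contamination)`, e.g. 11.7% → 20.1% with 36% uptake
and 15% contamination — an upper-bound style sensitivity, not an estimate.

## Hazard-ratio diagnostic

The compensatory-drop diagnostic estimates the between-arm incidence
hazard ratio over follow-up from the curves alone: `Λ(t) = −log(1 − F(t))`
per arm, local-linear regression of `Λ` on `t` (tricube kernel, fixed
bandwidth, default 2 years) for the derivative, and the ratio of slopes.
Grid points with non-positive denominator slope are masked as undefined
rather than clipped; points within one bandwidth of the support ends are
flagged as boundary estimates. The smoother and bandwidth are deliberately
exposed: derivative estimation at this smoothness level has no canonical
bandwidth, and the diagnostic is qualitative — excess ratio early, a dip
below 1 while the deficit plays out.

## Life tables

`LifeTable` holds annual hazards on a gapless integer-age grid. `qx`
columns convert via `h = −log(1 − qx)`; `mx` central rates are taken as
hazards directly. Ages beyond the table's maximum extrapolate flat at the
last value with a warning (needed when projecting 15 years from age 80
with a table ending in the early 90s). Single-year period tables only; no
abridged-table interpolation, no cohort tables.

**Synthetic English-male table.** National single-year life tables cannot
be bundled, so the package constructs a synthetic stand-in at call time:
log-hazard modelled as a quartic polynomial in age, with the five
coefficients solved (`scipy.optimize.fsolve`) so that 15-year death
probabilities at ages 50/59/64/70/80 equal the published 10/20/30/49/89%
exactly. For cause deletion a typical log-linear prostate-cancer mortality
schedule `2e−4 · exp(0.11(a − 60))` is subtracted — the right order of
magnitude and age gradient for English men. The constraints pin down
15-year integrals of the hazard, not its shape between and beyond the
anchor ages; by-age overdiagnosis computed on this table agrees with
values computed on the national table only to about two percentage points
(largest at age 80, where within-decade hazard shape matters most). Tests
against published by-age figures therefore use a 2.5-point tolerance.

## The trial simulator

The generator emulates the study conditions of a one-off-screen trial.
Per subject: an entry age (fixed or from a discrete distribution); a
latent counterfactual presentation time `t_clinical` drawn by inverse-CDF
from a piecewise-constant age-specific incidence hazard (possibly never);
a latent other-cause death time `t_death` from a life table; a lead time
`L`, exponential with configurable mean (Weibull via a shape parameter —
the lead-time law is not identified by trial data, and exponential is the
standard single-parameter choice); and administrative censoring at
`followup_max`. A screening-arm subject attends with probability
`attendance` (test sensitivity is folded in rather than modelled
separately); an attender whose cancer is in its detectable preclinical
phase at the screen — `t_clinical ≤ L` — is recorded screen-detected at
time 0. Everyone else observes the first of presentation, death, and
censoring. Ties between event and censoring at the same instant resolve
event-first (measure zero in continuous time; relevant only at the
administrative cutoff). The seed is mandatory and feeds a single generator
stream, so runs are exactly reproducible. Optional contamination applies
the same mechanism to a random control subset (their cancers surface at
time 0 but are not flagged screen-detected).

Oracle fields (`t_clinical`, `t_death`, `lead_time`, `overdiagnosed_true`)
are retained, so true overdiagnosis at any horizon is a direct count:
`min(t_death, horizon) < t_clinical` among the screen-detected. Under this
mechanism the net excess has a closed form — for exponential presentation
(rate λ) and exponential lead time (mean μ), `S1(k) = e^{−(λ+1/μ)k}` —
which tests exploit.

What the simulator does *not* emulate: cluster randomisation (CAP was
cluster-randomised; design effects are out of scope), PSA values and the
biopsy pathway, repeat-screen regimens, staggered entry, and any default
age gradient in lead time (an age-varying mean can be supplied, but no
gradient is asserted because none is identified). Passing recovery tests
therefore show the estimator chain is internally correct under the stated
mechanism, not that trial data meet its assumptions.

Default study conditions for recovery runs: 200,000 per arm, constant
incidence hazard 0.005/yr, lead-time mean 10 years, entry age 70, Gompertz
other-cause mortality `0.0008·e^{0.095(a−50)}`, follow-up 16 years
(so the 15-year curves are fully interior). At that size the Monte-Carlo
standard error of the excess ratio is ≈1 percentage point, and the
pipeline estimate agrees with the oracle within 3 such SEs; the same run
executes in seconds, which is why it also serves as the acceptance
script's simulation stage.

## Numerical choices and edge cases

* Internal arithmetic is in proportions; percent appears only at explicit
  boundaries (file ingestion with a mandatory scale flag, CI helpers that
  accept printed percent values).
* Negative excess is floored at 0 with a warning, never propagated.
* Ingested digitized curves may dip by up to 0.002 (proportion scale) from
  digitization jitter; dips are repaired by running maximum with a
  warning, larger violations rejected. The tolerance is this package's
  choice.
* `interpolate_yearly` is linear in `t` and forces `F(0) = 0`.
* Kaplan–Meier `F` is clipped infinitesimally below 1 so the cumulative
  hazard stays finite on fully-observed cohorts.
* Every warning-generating event (cap, floor, repair, extrapolation) has
  its own warning category, and the pipeline log records each occurrence.

## Known limitations

* Projection beyond the excess horizon `T` is deliberately unsupported:
  the trial identifies `S1` only to 15 years, and if the maximum sojourn
  time exceeds the follow-up the estimates are upper bounds.
* The published difference CI (−0.04 to 0.37%) is not numerically
  consistent with the published ratio bound (26.7%); the package
  reproduces the SE-propagation chain (which yields ≈26.6–26.7% depending
  on whether `R_A` is the rounded 1.19% or the raw count ratio) and does
  not attempt to resolve the discrepancy.
* Cluster-randomisation design effects would widen the trial CIs; the
  width-recovery method inherits whatever the published intervals contain.
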