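# Methods

## Problem setting

`sirest` targets cohort studies in which incident cases of a disease are
ascertained by linkage with a disease registry (dates of diagnosis
known), but no mortality follow-up or residence tracing exists: it is
unknown whether and when a member died of another cause or moved out of
the registry's catchment area. Crediting every non-case with follow-up
to the study end then overstates person-years, and the standardized
incidence ratio SIR = O/E is biased downward. The package reconstructs
expected person-years from population rates for the two unobservable
exits — mortality from causes other than the disease of interest (μ)
and out-migration (ν) — and propagates them into the SIR.

All rates are yearly probabilities stratified by age group × calendar
year (× optionally sex). The two exits are assumed independent within a
year, so the combined loss rate is the inclusion–exclusion

    γ = μ + ν − μν.

For realistic yearly rates (μ, ν ≤ 0.05) the additive shortcut μ + ν
differs from γ by at most μν ≤ 0.0025; the package always uses the
exact form.

## Person-years estimation

**Per individual (reference pathway).** Follow-up is split at every
calendar-year and age-group boundary (Lexis expansion, half-open
intervals, ACT/365.25 day counts; an event date contributes through the
end of its day). A non-case's expected contribution to a traversed cell
is

    E[py_cell] = S · py* · (1 − f · γ · py*),    S = ∏ (1 − γ' · py*')

over all earlier cells: `py*` is the maximal (raw) time in the cell, S
the probability the cell is reached, and `f = 0.5` the expected
within-year timing of a loss (uniform within the year; configurable via
`EVENT_TIME_FRACTION` / the `event_time_fraction` argument). For
whole-year cells entered on January 1 this reduces to the yearly
recursion `(1 − 0.5·γ_k)·∏_{κ<k}(1 − γ_κ)` implemented in
`yearly_expected_py`.

**Aggregate (iterative pathway).** `adjust_person_years` starts from
the raw table (all non-cases followed to study end) and discounts it
year by year: each year's expected person-year loss is subtracted from
the next year's raw cell before applying the loss factor. Aging is
handled by moving `1/w` of each loss into the next-oldest `w`-year age
group per year (`(w−1)/w` stays), the expected flow when a cohort is
spread uniformly within its age groups.

Two deliberate switches:

* `year_of_loss_credit` — the literal iterative rule applies `(1 − γ)`
  in the year of loss, whereas the per-individual accounting credits
  lost individuals their expected half year, `(1 − 0.5γ)`. The default
  is the literal rule (`0.0`); with `0.5` the aggregate accounting
  matches the per-individual recursion exactly on cohorts confined to
  one age group. The literal rule understates each year by a factor
  ≈ (1 − 0.5γ), i.e. ≈ 0.6 % in total at the default rates; both are
  exposed because each corresponds to a stated form of the procedure.
* `aging` — `False` keeps losses in their own age group (the stated
  no-aging form), appropriate when the cohort cannot cross a group
  boundary during follow-up.

**Degenerate input.** The `1/w`-per-year aging flow assumes members are
spread within age groups. A fully synchronized birth cohort (everyone
crossing a boundary the same year) violates that: losses remain in the
emptied group, intermediate cells go negative and are floored at zero
with a warning, and the aggregate total can overshoot by several
percent. Use the per-individual pathway (or one broad age group) for
such cohorts; the aggregate pathway is intended for realistic spread
cohorts.

Incident cases never pass through the estimation: their person-years
are exact (entry to diagnosis) and are added back before expected cases
are computed.

## SIR inference

E = Σ_ij py_ij λ_ij with reference incidence rates λ. O is Poisson;
`poisson_ci` provides the exact Garwood interval (inversion of the
Poisson tail probabilities via the χ² quantile identity; lower bound 0
at O = 0) by default and Byar's cube-root approximation as the
alternative — the two agree within 1 % for counts ≥ 20. The CI for the
SIR is the CI for the Poisson mean divided by E.

Because the denominator is estimated, an upper bound on Var(E) is
reported alongside. One individual's first-year person-time Y is 1 with
probability 1 − γ and uniform on (0, 1) given a loss, so
Var(Y) = γ(1/3 − γ/4) — about a third of the binomial γ(1 − γ), since
lost individuals contribute part of the year rather than zero. Later
years add the survival uncertainty of the preceding years, bounded by
(j − 1 + 0.25)·γ(1 − γ) in follow-up year j; random rates with
Var(γ) = σ² add σ² per year of exposure. The cell (i, j) of the
expected-case sum therefore contributes

    λ_ij² · p̂y_ij · (j − 1 + 0.25) · (1 − γ_ij) · γ_ij

to the Var(E) bound (equivalently E_ij·λ_ij·(…) with E_ij = λ_ij·p̂y_ij).
On the 1000-person reference cohort this bound is ≈ 10⁻⁴ of
Var(O) = E, so the default intervals treat E as fixed; the bound is
reported, never silently folded into the CI. When the aggregate pathway
supplies p̂y, j is read as calendar year minus the first contributing
year plus one — exact for a single entry wave, a labelled approximation
otherwise.

## Sensitivity analysis

`sensitivity_analysis` re-runs the pipeline under a family of labelled
scenarios: global (or per-stratum) multipliers on the migration and/or
mortality tables, plus a raw-person-years scenario that skips the
adjustment entirely. Raw person-years are the upper bound of the
denominator, so the raw scenario yields the minimal SIR of the family;
larger multipliers remove more person-time and push the SIR up. One
observed count O is shared by all scenarios. Multiple disease sites are
handled by running the pipeline once per incidence table, with no
multiplicity adjustment.

## Simulation harness

The simulator draws, for every individual and year, a single Bernoulli
event with probability 1 − (1−λ)(1−μ)(1−ν); given an event, the type is
chosen proportionally to (λ, μ, ν) and the timing uniformly within the
year. This discrete-annual model is chosen over piecewise-exponential
hazards deliberately: under it the half-year credit is the exact
conditional expectation of the within-year survival time, so
`yearly_expected_py` is an exact closed form for the simulated mean and
Monte-Carlo agreement is a sharp oracle rather than an approximation.

Per run the harness records exact person-years (simulated truth),
estimated person-years (closed-form expectation for every non-case —
losses being unobservable — plus exact case time), and biased
person-years (full horizon for every non-case). Summary statistics
(mean, SD, median, IQR) are computed across runs. The default
configuration is the reference study design: 1000 runs × 1000
individuals × 15 years, everyone entering 1990 at age 40, with
period-varying rates μ = 2, 3, 5 ‰, ν = 13, 10, 7 ‰ and λ = 0.5, 0.8,
1.2 ‰ over 1990–94 / 1995–99 / 2000–04. Reproducibility: a master seed
spawns one substream per run index, so extending `n_runs` preserves
earlier runs bit-for-bit.

What the synthetic generator does *not* emulate: real cohorts have
heterogeneous, sex-specific rates, mid-year entries, registry
completeness issues (e.g. death-certificate-only cases) and possibly
informative loss; passing tests demonstrate the estimator's internal
consistency under its stated assumptions, not robustness to violations
of them — that is what the sensitivity models are for.

## Numerical conventions

* Rates stored per-1; file scale (`per1`, `per1000`, `percent`)
  must be declared, never guessed.
* Half-open strata `[low, high)` for age and year; the top age group
  may be open-ended; no extrapolation outside the supplied domain —
  out-of-domain lookups raise.
* Day counts ACT/365.25; dates are whole days; the age-group boundary
  falls on the first day the exact age reaches the boundary.
* Within-year event timing expectation fixed at 0.5, configurable.
* Negative intermediate aggregate cells floored at 0 with a warning.
* Problem sizes in the test-suite: the full 1000 × 1000 × 15 study
  design runs in seconds, so tests use it directly except where a
  smaller cohort suffices for a structural property.

## Known limitations

* The aggregate iteration propagates only the cumulative loss through
  the previous year's cells; losses are not re-distributed further back,
  matching the stated procedure.
* Var(E)'s year index j is exact only for single-entry-wave cohorts.
* No smoothing or interpolation of rate tables; callers must supply
  covering tables.
* Left truncation beyond the entry date, time-varying covariates and
  competing diagnosis types are out of scope.
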