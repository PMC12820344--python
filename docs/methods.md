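# Methods

## Model

The population is modelled as a discrete-time multistate process over four
living states — (1) healthy & working, (2) healthy & not working, (3) not
healthy & working, (4) not healthy & not working — plus absorbing death.
The default transition structure permits every ordered pair of distinct
living states and death from each living state (16 modelled transitions);
recovery of both health and work is allowed, death is not left.

One transition step spans 12 months.  Exits from living state *i* follow a
multinomial logit with the self-transition as the reference category,

η_ij(a, x) = α_ij + β_ij·(a − 50) + γ_ijᵀx,

age *a* evaluated at the start of the step, *x* optional binary covariates
held at their value at the origin interview of the interval.  Intercepts are
reported at a reference age of 50 (the anchor of all expectancies); this is
a pure reparametrization of a raw-age intercept and can be converted by
α − 50β.  Age enters linearly on the logit scale; with positive death
slopes near 0.09/year this reproduces Gompertz-like mortality doubling
roughly every 8 years.

### Interval-censored likelihood

States are observed only at interviews roughly 24 months apart and at
month-resolution death dates.  An interval from a known state at one
interview to the next informative observation contributes the corresponding
entry of the ordered product of step matrices, ages advancing per step:

* destination is a known living state — the matrix-product entry;
* destination is "alive, state unknown" (code −1) — the row summed over the
  living states.  A −1 wave strictly between two informative observations is
  implied by the later one and carries no extra information; the likelihood
  chains across it (as it does across −2 waves, which are uninformative by
  construction);
* death at a known month — remain among the living until the start of the
  final step, then move to dead within it (the death month localizes the
  event to one step);
* persons alive at their last interview are right-censored there; a single
  observation contributes nothing.

Intervals that are not whole multiples of the step end with a partial step
whose exit odds are scaled by the elapsed fraction of the step
(exp(η + ln f)); this is exact at f = 1, tends to the identity as f → 0,
and keeps the likelihood continuous in the observation dates.

Each person's log-likelihood is multiplied by their longitudinal survey
weight.  The total is maximized by L-BFGS with an analytic score (the exact
derivative of the product-matrix entries through the softmax), after an
internal linear change of variables — intercept read at the mean observed
step age, slope scaled by the age SD — that removes the near-collinearity
between intercepts and slopes; the transformation is undone exactly before
reporting.  Convergence requires the projected-gradient norm below 1e−5 or
relative likelihood change below ~1e−11.  Default starting values are
intercepts −4 (rare transitions), slopes and covariate effects 0.  The
covariance is the inverse observed information, obtained by central finite
differences of the analytic score at the optimum (step 1e−5, symmetrized);
a singular information matrix is reported as "covariance unavailable",
never silently replaced.

### Expectancies

From each living starting state at the anchor age (50), occupancy vectors
are propagated by repeated step-matrix multiplication to a horizon of 60
years (age 110); conditional expectancies e_ij are trapezoidal integrals of
occupancy (average of the step's endpoint occupancies × step length).  A
warning is raised if living occupancy above 1e−4 remains at the horizon.
Population expectancies weight starting states by the survey-weighted
observed prevalence in the age window [50, 51); the window is configurable
(e.g. [50, 55)) because refreshment designs need not include respondents at
exactly 50.  HWLE is the population expectancy of state 1, and life
expectancy is *defined* as the sum of the four expectancies, so the sum
identity is exact by construction.

For integration-refinement checks, a step may be subdivided into m
sub-steps using the principal matrix root M^(1/m): the product over one
step reproduces M exactly, so finer grids refine only the occupancy
integration, never the transition law.  (The model *is* a 12-month-step
chain; sub-stepping is interpolation of that chain.)

### Uncertainty

SEs and 95% intervals come from parametric simulation (1,000 draws by
default, deterministic per seed): parameter vectors from N(estimate,
covariance), and — because the age-50 prevalence is itself estimated from a
few hundred respondents and its sampling noise is a first-order variance
component of HWLE — prevalence weights from a Dirichlet centred on the
observed weights at the window's Kish effective sample size
(Σw)²/Σw².  The full expectancy pipeline is recomputed per draw; SE is the
draw SD and the interval the 2.5/97.5 percentiles.  The prevalence
component can be disabled to isolate parameter uncertainty.

## Panel preparation rules

* **Health**: three activity-limitation items; any "yes" → not healthy; all
  three "no" → healthy; no item answered → missing.  A partially answered
  record with no "yes" cannot be confirmed healthy and is treated as
  missing.
* **Work**: "working now" → working; any other stated answer (laid off,
  unemployed, disabled, retired, homemaker, other) → not working.
* **State coding**: dead → dead; both classifications known → 1–4; either
  missing → −1; unknown vital status → −2.
* **Arthritis** is irreversible: answers are first imputed from the nearest
  wave (earlier wave wins ties, so no future information is used), then a
  running maximum enforces "once reported, always present"; absent an
  earlier "yes", waves at and before an explicit "no" are 0.
* **Obesity**: BMI ≥ 30 (inclusive), metric kg/m² or US 703·lb/in², from
  baseline height and per-wave weight; implausible heights (outside
  1.2–2.3 m equivalent) warn and go missing; missing values are imputed
  nearest-wave.
* **Dates** at month resolution, day fixed at 15 for age arithmetic; ages
  are exact fractional years (days/365.25).  Missing birth month → June.
  Missing death month → June, or December if June precedes a participation
  date; a recorded death month contradicted by a later interview in the
  same year moves to December.  Death records without dates are ignored.
* **Weights**: each person carries the first non-zero cross-sectional
  weight from a wave at age ≥ 50; no qualifying wave → ineligible.
* **Exclusions**: missing any fixed covariate (sex, education, ethnicity,
  region); a time-varying covariate missing at every wave; no qualifying
  weight.  Observations before age 50 are dropped.  Each exclusion is
  logged per person with its reason.

US states map to the four Census regions (50 states + DC); unknown names
are a coding error, not a silent fourth category.  Ethnicity "other" is
retained through prep but skipped in ethnicity-stratified runs (small-n
convention for this design).

## Synthetic cohort generator

The generator emulates the design of a biennial US ageing survey: entry
ages uniform over 50–60 at month resolution (refreshment is emulated by the
entry-age spread, not by staggered enrolment), 14 waves 24 months apart
starting 1994, simulation on the estimator's 12-month step grid (a finer
grid is configurable to probe discretization), irreversible arthritis onset
with a logistic age hazard, obesity switching on/off with small per-step
rates, i.i.d. positive survey weights (constant 1 by default), unknown-state
(−1) and skipped-wave (−2) rates of 5% each (arbitrary, configurable — the
source survey's participation pattern is not public), and death dates at
the end of the fatal step.

Entrants older than 50 draw their initial state from the age-50
distribution evolved (conditional on being alive, at population-average
covariates) to their entry age, so the synthetic population is
age-consistent and state prevalence at a fixed age carries no calendar
trend — which is what makes the calendar-period sensitivity check
meaningful on synthetic data.

Default ground-truth parameters were chosen once for realism: ~5%/year exit
from work while healthy rising with age, ~10%/year re-employment at 50
falling with age, health transitions of a few percent per year, mortality
0.2–0.7%/year at 50 with slope 0.09–0.095/year.  They imply a life
expectancy at 50 near 29 years and an HWLE near 6.3 years with ~55% of
50-year-olds healthy and working.  These are plausible magnitudes, not
calibrated estimates.

What the generator does **not** emulate: questionnaire skip logic, proxy
interviews, design-based weight construction, informative missingness
(missingness is MCAR), calendar-period effects, within-step covariate
changes, or heaping/recall error in dates.  Passing recovery tests
therefore shows the estimator is correct under its own assumptions on
MCAR-missing, interval-censored data — not that those assumptions hold in
any particular survey.

## Stratified analysis

The default reporting mode refits the model separately per stratum (one
small model per table row), mirroring tables whose rows are separate
populations.  Fixed covariates stratify at the person level; the
time-varying ones (arthritis, obesity) assign each transition interval by
its value at the interval's origin wave and each prevalence observation by
its value at that wave.  A pooled mode instead fits one model with binary
covariates on every logit and evaluates expectancies per covariate profile,
remaining covariates held at weighted sample means.  Strata with fewer than
50 transition intervals are skipped with a logged warning rather than
fitted unidentifiably.  An empty age-50 prevalence window widens to five
years with a warning.

The calendar-period sensitivity check tabulates survey-weighted state
prevalence by survey year for respondents within ±1 year of target ages
(55, 60, 65), and flags a state/age cell "trend" when its range across
years exceeds 10 percentage points — an automated stand-in for a visual
trend assessment.  Cells with fewer respondents than a configurable
minimum are reported missing rather than allowed to drive flags.

## Validation design and problem sizes

Oracles are independent of the paths they check: exhaustive path
enumeration (≤ 6 steps) against the matrix-product likelihood at 1e−12; a
closed-form binomial MLE on a two-state chain; the fundamental matrix
N = (I − Q)⁻¹ for time-homogeneous expectancies (trapezoid sits exactly
half a step below the visit count on the diagonal); 50,000 simulated full
trajectories scored with the same trapezoid convention (a within-step
transition credits half a step to each endpoint state) for the population
expectancies.

The replicate studies use 100 cohorts of 2,000 individuals over 14 biennial
waves for Wald-interval and expectancy-interval coverage (fits initialized
at the generating values for speed; a separate test verifies that default
initialization reaches the same optimum), 20 cohorts of 5,000 for the bias
check (bias under half a replicate SD plus a 2·SD/√R estimation-noise
allowance), and 10 cohorts of 1,500 for the directional arthritis check.
These sizes keep the default suite to roughly a quarter hour on one CPU
while leaving each check statistically meaningful.

## Known limitations

* The logit-linear age effect is an assumption, not a finding; strongly
  non-Gompertz hazards would need splines or piecewise terms.
* Partial-step odds scaling and midpoint-free age evaluation (age at step
  start) are conventions; both match the generator, and refinement checks
  bound their effect, but other software may differ at the margin.
* Stratifying a time-varying covariate at the interval origin discards
  within-interval onset; the pooled-covariate mode is the alternative.
* CIs treat the prevalence window as independent of the fitted parameters;
  the two share respondents, a second-order effect at these sizes.
* The delta-method covariance of the reference estimation tradition is
  replaced here by parametric simulation; both target the same asymptotic
  variance.
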