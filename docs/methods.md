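# Methods

## The costing model

The engine implements time-driven activity-based costing (TDABC) for a
surgical care pathway. A procedure is decomposed into a process map of
micro-activities *i*, each staffed by resources *j* in quantities
X<sub>j|i</sub> (fractional quantities are allowed: 2.5 nurses means one
nurse present half the time). Each non-consumable resource has a capacity
cost rate

CCR<sub>j</sub> = period cost<sub>j</sub> / (theoretical capacity<sub>j</sub> × practical fraction),

in EUR per minute, with the practical fraction defaulting to 0.8 — the
usable share of nominal availability after downtime and breaks. The cost of
a patient's procedure is

C<sub>pt</sub> = Σ<sub>i</sub> β<sub>i</sub> Σ<sub>j</sub> X<sub>j|i</sub>·CCR<sub>j</sub> + y,

where β<sub>i</sub> is the chrono-analysed duration of activity *i*
(minutes) and *y* the directly attributed consumables (the surgical kit).
Indirect costs (operating room, platform rental and maintenance) and
personnel are allocated through time; the kit is the only direct cost in
the bundled fixture. All arithmetic is carried in double precision;
rounding to cents happens only in exported tables.

Assumptions: costs are linear in time (no fixed per-case setup charges
beyond what the process map encodes); resources staffed on an activity are
engaged for its entire duration; capacity cost rates are constant over the
study horizon.

### Arm-dependent resources

Arms are opaque labels and the engine is k-arm agnostic (comparisons are
pairwise). Platform rental differs by arm while activities are shared, so a
staffing key may contain the placeholder `{arm}`, resolved against the
patient's arm at costing time and validated against every declared arm at
load time. Per-arm kits follow the `kit_<arm>` naming convention in the
patient loader.

## Time equations

Per activity, observed duration is regressed (ordinary least squares) on
indicator covariates: platform arm (first arm of the map as reference) and
lymph-node dissection (LND). Effects with two-sided p ≥ 0.05 are reported
but flagged non-significant; the screen is per-effect and unadjusted, as is
conventional when the comparison table itself reports raw p-values.
Covariates constant in the cohort make the design singular and are skipped
with a warning. Predictions are clipped at zero with a warning — a negative
sum indicates extrapolation outside the observed covariate space.

## Two-arm comparison

Every comparison row carries mean, sample SD (n−1 denominator), min, max
per arm, plus a Welch two-sample t-test and a Mann–Whitney U test
(asymptotic normal approximation with tie correction), both two-sided. The
Welch variant was chosen because the arms show clearly unequal dispersions;
the published analysis did not specify the t-test flavour. No
multiple-testing correction is applied (rows are reported with raw
p-values). Degenerate zero-variance samples follow an explicit convention:
p = 1 when means are equal, the smallest positive double when they differ.

Percent differences follow the conventions of the published tables, row by
row: activity, phase, category, case-time and length-of-stay rows report
(larger − smaller)/larger × 100 (the cheaper arm's relative saving); the
total row reports (first arm − second arm)/second arm × 100, signed.

The LND micro-activity is excluded from the main comparison (its cost is
analysed in the LND subgroup separately), because performing LND does not
bear on the between-platform question and would add within-arm variance.

The learning-curve split compares the first *k* cases of an arm (enrollment
order, `case_index ≤ k`) against the rest; the fixture uses k = 22, the
proficiency threshold reported for the Hugo arm. Length of stay is compared
with the same test battery but kept outside the cost equation.

## Deterministic sensitivity suite

The suite operates on an arm-level affine cost model — baseline total per
arm plus named parameters, each entering one arm's total as
coefficient × (value − baseline). This mirrors deterministic
health-economic practice and makes every analysis closed-form and exactly
reproducible. Parameter kinds reduce uniformly to this shape:

* kit cost — coefficient 1;
* per-case platform (rental) allocation — coefficient 1; a relative change
  in the annual fee is the same relative change in the per-case allocation,
  by linearity of the CCR;
* activity duration — coefficient equal to the activity's summed staffed
  CCRs (EUR/min); equivalently, surgery time can be carried as its
  time-driven cost with coefficient 1, which is what the bundled baseline
  model does.

One-way analysis perturbs each parameter to (1 ± f) × baseline (default
f = 0.30) and sorts tornado entries by swing, ties broken lexicographically.
Threshold analysis solves for cost parity in closed form (a bisection
fallback is provided for any monotone evaluator); parity values that would
require a negative parameter are flagged infeasible rather than raised.
The two-way frontier is the parity line in a two-parameter plane with
cheaper-arm region labels; two parameters of the same arm are rejected as
degenerate. Scenario matrices evaluate one arm's total over a grid of
relative changes, rendered kit +30% → −30% top-to-bottom and rental
−30% → +30% left-to-right for byte-stable CSV output. Parity claims are
verified to 1e-6 EUR.

The bundled baseline model uses the published arm totals
(€4,979.21 / €3,511.73) as baselines. The published case-time + kit
decomposition of the Hugo arm (1,926.00 + 1,586.00 = 3,512.00) differs from
its published total by €0.27 — a rounding artefact of the source tables —
so frontier intercepts computed from totals and from case-times differ by
the same €0.27; the package always derives them from the model it is given.

## Synthetic-cohort generator

The generator emulates the statistical structure the analysis assumes, so
every stage is testable without patient-level data (which are restricted
for the reference trial):

* **Durations** are truncated normal, truncated at zero by default, and
  moment-matched: a two-parameter solve recovers the underlying
  location/scale such that the *truncated* distribution has exactly the
  stated mean and SD. (A normal truncated at zero cannot reach a
  coefficient of variation of 1; infeasible targets raise.) Published
  min/max values are reference information and are not imposed as
  truncation bounds — hard two-sided bounds would distort the matched
  moments.
* **Within-case correlation**: activities may share a correlation group;
  members share one uniform draw per patient (comonotonic copula). Because
  calibrated micro-activities within a phase share a coefficient of
  variation, the phase total's SD is exactly the sum of member SDs, which
  is what lets a 19-step map reproduce phase-level dispersion. Independent
  micro draws cannot: per-step CVs would have to exceed the truncated
  normal's feasible range. Scientifically this encodes a per-case speed
  factor — a slow case is slow across a whole phase.
* **Kit cost** is constant within arm. **LND** is drawn per patient
  (fixture probabilities 0.46/0.52) with its own duration (40 ± 10 min) on
  the LND console step; non-LND patients record 0 minutes so chrono
  coverage is complete by construction.
* **Learning curve**: selected activities of one arm are inflated for
  cases up to the proficiency index (default 22), by a step factor
  (default) or a linearly decaying one.
* **Length of stay** per arm is truncated normal at the stated moments.
* **Determinism**: one seed; `SeedSequence(seed)` spawned once per arm,
  then a fixed documented draw order per patient (LND indicator, LND
  duration, LOS, one uniform per group, one per ungrouped activity).
  Identical spec + seed gives bit-identical cohorts across platforms.

### Fixture calibration

Patient-level durations for the reference trial are not public; the fixture
inverts the published *cost* moments through the staffed rates
(duration = cost / Σ X·CCR), per micro-activity and arm. Choices made once
and documented here:

* **Capacity annualization** (the source states 12 h/day theoretical for
  platforms and the 80% practical convention, but not operating days or
  personnel hours): platforms 300 days × 12 h (216,000 min/yr), operating
  room 250 days × 12 h (180,000 min/yr), personnel 100,000 min/yr. Period
  costs (personnel €22k–€105k, platform fees €335k/€415k, OR €273k) were
  set so that per-case platform and operating-room cost levels land within
  ~2% of the published resource-category breakdown and implied mean case
  times come out ≈179 min (da Vinci) vs ≈219 min (Hugo) — a ≈40-minute
  platform gap, matching the reported total platform effect on time.
* **Micro weights**: published cost moments are per macro phase. Micro
  activities receive fixed mean-cost weights within each phase; the trocar
  step's weight is derived from published surgery-total vs console-only
  means (trocar placement is the only non-console surgery step); remaining
  weights are a plausible clinical reading, and all phase-level and
  console-level results are invariant to them.
* **Learning curve**: Hugo surgery and prep-positioning steps are
  calibrated to the post-proficiency (last-28) means and inflated for the
  first 22 cases by the published early/late mean and SD ratios
  (≈1.236 on means). Room setup and anesthesia are held constant, as their
  published early/late differences are non-significant.

### What the generator does not emulate

Clinical outcomes, margins, complications and readmissions (one per arm in
the trial, excluded from its costing); between-phase correlation of
durations; surgeon identity or any random effects; non-normal duration
shapes (e.g. heavy right tails beyond what truncation induces); drift other
than the configured learning curve. Passing tests therefore show that the
pipeline recovers what the generator encodes — calibrated first and second
moments, injected covariate effects, orderings — not that real chrono data
meet these assumptions.

## Numerical choices

* Conservation (Σ categories = Σ activities + y = total) holds to 1e-9
  relative and is asserted in tests.
* Zero-variance p-value conventions as above; Mann–Whitney with all
  observations tied returns p = 1.
* Tornado tie-break: lexicographic on parameter name. Parity tolerance
  1e-6 EUR.
* Missing chrono records contribute zero cost and are listed in a coverage
  report — loud, not fatal; structural errors (orphan ids, negative
  durations, duplicate records) are fatal.
* Currency is kept at full precision internally; tables round to cents,
  shares to 0.1 percentage points (rounded shares sum to 100 ± 0.1).

## Problem sizes

Tests run at trial scale (50 patients per arm) for cohort-level checks, 200
replicates for effect-recovery coverage (on a compact four-activity map),
5,000 patients per arm for the law-of-large-numbers calibration check, and
20–40 replicates for decision-agreement and bias checks. The acceptance
script recomputes deterministic quantities from the published inputs and
measures cohort quantities on one 50 + 50 simulated cohort under the given
seed.

## Known limitations

The affine sensitivity model is exact only for parameters that enter
linearly (all the bundled ones do); nonlinear capacity effects (e.g.
utilization-dependent CCRs) are out of scope. The calibrated fixture
reproduces published phase-level moments, not the unpublished
micro-activity table of the source appendix. The comparison module offers
no survival or readmission analysis, no discounting, and no probabilistic
sensitivity analysis — the deterministic suite is the scope; a Monte Carlo
layer over parameter distributions would be a natural extension.
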