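# Methods

This note documents the models, algorithmic constants, design choices and
limitations of `mvpatiming`, in the spirit of a statistical package's model
documentation. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. Event definition and the person-period risk set

For participant i with valid days d, the person-specific anchor is
m_i = mean over included days of daily MVPA minutes. Within a day, time is
discretised into clock-hour intervals; interval t is the span
(t−1:00, t:00] and is labelled "Before t" in every output. The event for a
day is the smallest t whose cumulative MVPA (sum of hourly MVPA through
interval t, counted from midnight) reaches m_i, with the ≥ convention:
exactly attaining the average counts ("accumulating one's average" is
attainment, not exceedance). Days whose total never reaches m_i are
censored at the end of the risk window.

The default risk window is intervals ending 9 AM through 11 PM, with 8 AM
as the reference boundary; it is configurable, echoed in every output, and
chosen because the emulated design observed no attainment before 8 AM or
after 11 PM. Conventions fixed here and printed in output headers:

* an event that would occur before the window start is coded at the window
  start (it is logged; in the emulated design this is rare);
* days with zero worn-awake minutes inside the window contribute no rows —
  they carry no risk information;
* participants with m_i = 0 would trivially "attain" at the first wear hour
  of every day; they are excluded from modelling by default and logged.

The person-period table has one row per day at risk per hour, event ∈
{0, 1}, with at most one event row per day, always terminal. Covariates
(sex, BMI category, sports) repeat on every row; school day varies by day.

## 2. Preprocessing constants

All constants live in `AlgorithmParams`; none are hard-coded, and the run
log echoes the values used.

* **Nonwear** (per-minute counts): a minute is nonwear iff it lies in some
  window of ≥60 min in which every count is zero except ≤2 interrupt
  minutes, each with count <100. This "any qualifying window" semantics is
  implemented exactly (prefix-sum scan over all 60-min windows) and is
  cross-checked against a brute-force oracle in the tests.
* **Sleep** (per-minute counts): the five-term linear score
  SI = 7.601 − 0.065·AVG − 1.08·NATS − 0.056·SD − 0.703·LG, where AVG is
  the mean count over the centred 11-min window, NATS the number of minutes
  in that window with counts in [50, 100), SD the population standard
  deviation over the scored minute and its 5 predecessors, LG = ln(count+1)
  of the scored minute; sleep iff SI ≥ 0. Edges are padded with zeros.
  Scoring is restricted to a configurable overnight span (default
  8 PM–10 AM); outside it minutes are wake regardless of score. Rationale:
  unrestricted scoring labels sedentary afternoons as sleep, destroying wear
  time; the restriction is a documented choice, not a claim about the
  motivating study's configuration.
* **Intensity** (per-epoch counts at the cutpoints' native 5 s epoch,
  wrist vector magnitude): sedentary <306, light ≥306, moderate ≥818,
  vigorous ≥1969 counts/5 s; boundary counts go to the higher class. MVPA =
  moderate ∪ vigorous. Shorter epochs are re-aggregated by summation;
  longer epochs are rejected (disaggregation is ill-posed).
* **Inclusion**: wear day valid iff worn-awake ≥480 min (8 h, boundary
  inclusive); the first 3 *calendar days containing any wear* are trimmed
  per participant (reactivity refers to study days, not valid days);
  participants with <4 remaining valid days are excluded. Kept summaries
  carry a `reactivity_screened` marker so that re-applying the rules is the
  identity (idempotence) rather than trimming three more days.
* Epochs are attributed to the clock hour containing their start; all
  timestamps are naive local clock time (a DST-transition day is processed
  naively).

## 3. The hazard model

On the person-period table the discrete-time hazard is

logit h_i(t) = Σ_k β_k t^k + γ'x + (δ ⊗ t-polynomial)'x·t-terms + u_i,
u_i ~ N(0, σ_u²),

with k ≤ 3, x the moderator dummies, and a single person-level random
intercept (days within persons share u_i; a day-level intercept is not
identifiable with ≤1 event per day). Estimation maximises the marginal
likelihood; the 1-D integral over u_i is approximated per person by
adaptive Gauss–Hermite quadrature centred at the posterior mode with the
Hessian-based scale. Node count is configurable (default 9; 1 node is
exactly the Laplace approximation, matching the estimator of the emulated
study; estimates move by <1e−3 between 9 and 15 nodes on test fixtures).

Numerical choices:

* internal time coding u = (t − 8)/10 before powering, to condition the
  cubic design; all reported coefficients/covariances are back-transformed
  to the original hour scale by the exact binomial-expansion map, so
  downstream quantities are invariant to the internal coding;
* outer optimisation by L-BFGS-B over (β, log σ_u) with finite-difference
  gradients, log σ_u bounded in [−10, 3] (the lower bound is numerically
  σ_u = 0); inner mode-finding by vectorised per-person Newton;
* the covariance matrix is the inverse of a central-difference observed
  information at the optimum (Wald machinery; all CIs are symmetric on the
  log-odds scale, z = 1.959964);
* optimizer failure never raises: `converged=False` with diagnostics;
* constant or collinear design columns (e.g. a moderator with a single
  observed level) are dropped with a warning and the fit proceeds;
* all-event or all-censor tables are rejected (separation);
* starting values come from the fixed-effects logistic fit (Newton/IRLS),
  which is also the exact estimator when `random_intercept=False`.

Model selection: degrees 1→2→3 are compared by likelihood-ratio tests
(χ² on the −2LL difference, floored at zero); degree k+1 replaces k iff
p < 0.05, stopping at the first non-significant step. Moderated models
inherit the selected base degree (a flag allows re-selection) and add the
moderator's dummies plus dummy×t^k interactions, one moderator per model,
estimated separately. School day enters the same structure as a row-level
covariate.

## 4. Reporting quantities

With the random intercept set to 0 (median-person interpretation;
a population-averaged variant integrating over u is deliberately out of the
default path):

* OR(t) = exp(η(t) − η(8 AM)); CI from the delta contrast c'Σ̂c with c the
  design-row difference. The reference row is exactly 1 with a degenerate
  [1, 1] interval.
* h(t) = expit(η(t)).
* S at row k = Π_{j<k} (1 − h_j), the product over *strictly earlier* rows,
  with the reference row first (its S is 1 − hazard of its predecessor,
  taken as 0). This lag convention is the only one arithmetically
  consistent with the published hazard/survival table this package uses as
  its validation input (all 16 rows agree to the printed rounding of
  ±0.01), and it is stated in every output header.
* Group comparison: two groups differ significantly at an hour iff their
  95% CIs are disjoint (max of lower bounds > min of upper bounds). This
  mirrors the motivating analysis style; it is conservative relative to a
  direct interaction contrast and involves no multiplicity correction —
  both properties are inherited deliberately.

## 5. Decision points

* Overall window: the maximal contiguous run of rows with hazard ≥
  (1 − rel_tolerance)·max hazard (default rel_tolerance 0.10), or
  alternatively the span-length window of steepest survival decline
  (default span 3 rows). Ties break toward the *later* run
  (evening-priority: the substantive recommendation privileges the late-day
  window). With rel_tolerance = 0 the window is exactly the argmax run.
* Moderator windows require both criteria: (1) ≥1 hour with disjoint CIs;
  (2) the differences at those hours run in the registered direction.
  The default hypothesis registry marks sports participation and school day
  directional (participants/school days expected higher) and sex and BMI
  exploratory — an exploratory moderator passes criterion 2 automatically
  once criterion 1 holds with a consistent favored group. Windows operate
  on row labels, never raw clock spans, because prose mappings from rows to
  clock windows are ambiguous; reports print both the labels and the
  interval convention.

## 6. The synthetic cohort generator

`simulate_cohort` emulates the study design the package targets: 113
adolescents × 20 days of wrist vector-magnitude counts at 5 s epochs.
Structure per participant-day (1440 minutes):

* person-level daily MVPA target m_i ~ Gamma with mean 30.91 and SD 30.94
  (floored at 1 min); day totals M_id ~ Gamma(shape 1, mean m_i), i.e. an
  exponential day-to-day law. The shape-1 choice is deliberate: it keeps
  person means controlled while making the fraction of days on which a
  person meets their own mean equal e^-1 ~ 0.37, the rate characteristic of
  observational adolescent cohorts of this design;
* sleep span with onset ~ N(11:15 PM, 30 min) and wake ~ N(7 AM, 30 min);
  sleep minutes are zeros with occasional small movement spikes (one epoch
  of 5–45 counts with probability 0.4/min), low enough to score as sleep
  and sparse enough that sleep never forms a 60-min zero run (so sleep and
  nonwear remain distinguishable);
* Poisson(0.7)/day nonwear blocks of 60–180 min of exact zeros in the
  awake span;
* round(M_id) MVPA minutes allocated among worn-awake minutes with
  probability proportional to an hourly circadian profile; MVPA epochs draw
  818 + NegBin(mean 600, k=5) counts (guaranteed ≥ the moderate cutpoint),
  other awake epochs draw truncated-Gamma counts capped at 817 (guaranteed
  below it). The count law is recorded in the truth record. This makes
  realised daily MVPA equal the allocated minutes, so the population mean
  is controlled exactly and preprocessing recovers it;
* the default profile peaks at 6 PM with modest morning/midday mass;
  additionally a fraction of days (default 0.12) are "morning-active" days
  following a separate late-morning-peaked profile with negligible mass
  before 9 AM — without this day-type mixture, events almost never occur
  before noon, contradicting the event-hour distribution the generator is
  meant to emulate, while mass before 9 AM would contaminate the 8 AM
  reference interval;
* moderator timing effects: whole-hour circular shifts of the profile
  (males −3 h, sports +1 h, school days +1 h) plus multiplicative
  morning-day propensity factors (sports ×0.5, school days ×0.5). These
  defaults plant the hypothesized structure the pipeline should recover:
  males earlier-shifted (their fitted hazard peaks earlier, and their odds
  of late-evening attainment are detectably lower than females'), sports
  participants and school days later-shifted. The male shift size was
  chosen so that the sex difference clears the deliberately conservative
  CI-nonoverlap detection rule at the emulated cohort size; smaller shifts
  produce the same direction but are not reliably flagged by nonoverlap;
* a single seed drives everything; per-participant substreams are spawned
  deterministically from it, so subsetting participants is reproducible and
  identical configurations are byte-identical.

What the generator does **not** emulate: raw 30 Hz waveforms and the
device's band-pass/count conversion (generation starts at epoch counts);
autocorrelated activity bouts within the hour; seasonal structure; wear
compliance that declines over the protocol; BMI-dependent activity levels.
Passing tests therefore demonstrate pipeline correctness under a controlled
truth, not validity of the substantive findings for real adolescents.

One consequence worth knowing: because the event anchor is each person's
*own* mean, the event-timing distribution is largely self-normalising —
under the exponential day law every person meets their mean on ~37% of
days regardless of m_i — so the fitted random-intercept SD on synthetic
cohorts is genuinely near zero. The random-effect machinery is exercised
instead by `simulate_person_period`, which plants a known σ_u directly.

`simulate_person_period` bypasses the count level entirely and draws the
person-period table from an explicit `TrueHazardModel` (polynomial
log-odds, optional covariates and interactions, Gaussian random intercept),
which is what the estimator tests use for parameter recovery, coverage and
LRT calibration.

## 7. Test problem sizes

The test suite exercises: survival arithmetic on the 16 published hazard
rows; brute-force oracle equivalence on 500 randomised inputs per
classification stage; fixed-effects oracle equality to 1e−4; Wald coverage
over 200 replications of 500 persons × 10 days (risk window of 6 hours,
σ_u = 0.6 — coverage within 3 Monte-Carlo SEs of 0.95); LRT null
calibration over 500 replications (Kolmogorov–Smirnov at α = 0.01); cubic
selection consistency over 100 replications at a pronounced curvature; and
a full end-to-end run at the emulated design scale (113 × 20). One test
cross-validates the mixed estimator against lme4's `glmer` (nAGQ = 9).

## 8. Known limitations

* The hazard model treats hours as conditionally independent given u_i;
  within-day serial dependence beyond the risk-set structure is not
  modelled.
* One event per day, no sub-hour timing, no recurrent events.
* The CI-overlap rule is conservative; a joint interaction LRT is available
  via nested fits but is not the default decision rule.
* Wald coverage of the random-intercept SD itself is not asserted
  (boundary-adjacent sampling distribution); σ̂_u is reported without an
  interval.
* The preprocessing algorithms use transcribed standard constants; sites
  with different devices/epochs must supply their own `AlgorithmParams`.
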