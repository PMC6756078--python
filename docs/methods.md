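# Methods

## The model

After an allogeneic transplant for MDS/sAML a patient occupies one of five
states: event-free (EF), alive after relapse/progression (R), dead after
relapse, dead of population causes without relapse, dead of excess causes
without relapse. The last two together are non-relapse mortality (NRM).
The central assumption of the decomposition is the standard one of relative
survival: the hazard of *population* death for a patient equals the hazard
of an age-, sex-, country- and calendar-year-matched member of the general
population, read from period life tables. Whatever the cohort's observed
NRM hazard carries beyond that matched hazard is *excess* mortality,
interpreted as treatment-related mortality (TRM). No cause-of-death
adjudication is used anywhere — the split is purely population-based.

## Life-table conventions

* Annual death probabilities convert to hazards as `h = −ln(1−q)`, constant
  within each one-year age × calendar-year Lexis cell. Cumulative hazards
  are then exact piecewise-linear functions of follow-up time, and a
  subject advances along the Lexis diagonal (attained age and calendar year
  move together); fractional cell crossings are handled exactly.
* Ages above the terminal row use the terminal row; years outside the grid
  clamp to the nearest boundary. Clamping is counted and surfaced
  (`ClampCounter`), never silent. Time is in years (1 y = 365.25 d).
* Expected survival uses the **Ederer II** estimator: the population hazard
  is averaged over the subjects still under observation, so the expected
  curve inherits the cohort's censoring pattern. Ederer I/Hakulinen are not
  implemented; Ederer II is the natural companion of the risk-set-based
  decomposition below, and the estimator label is carried in the output so
  the choice is explicit.

## The decomposition estimator

On the grid of all observed exit times (events *and* censorings, so the
population integrals track the risk set closely):

* `dΛ_nrm(t_j) = d_nrm,j / Y_EF(t_j)` — observed event-free death hazard;
* `dΛ_pop(t_j) = Σ_{i∈risk set} H_pop,i(t_{j−1}, t_j) / Y_EF(t_j)` — the
  matched cumulative hazard of the interval, averaged over the risk set;
* `dΛ_excess = dΛ_nrm − dΛ_pop`, **not floored at zero**: negative
  increments occur whenever fewer deaths are observed than the tables
  predict, and flooring would break the identity
  `P_pop + P_excess = CIF_nrm` (Aalen–Johansen), which holds here to 1e−8
  by construction and is asserted in the tests.
* Product-integration through the five states gives stacked probabilities
  that sum to one at every grid time. Post-relapse population mortality is
  computed and carried internally but merged into death-after-relapse for
  reporting — after relapse the prognosis is so poor that its population
  component is negligible. Displayed probabilities are clipped to [0, 1];
  internal arrays are not.
* State-occupation probabilities from this scheme are consistent even when
  the underlying process is non-Markov (the generator's post-relapse clock
  is semi-Markov), which is why the estimator can be validated against the
  simulator at scale.
* Uncertainty for stacked components, when requested, is a nonparametric
  bootstrap over subjects (default 200 replicates, seeded); no closed-form
  variance is attempted for the composite decomposition.

Landmark analyses restrict to patients alive (OS population) or alive and
event-free (EF population) at 2 or 5 years, reset the clock, and — for the
OS population — carry previous relapse as a binary covariate. Subjects
censored before the landmark are excluded; the matched hazards are still
evaluated at the correct attained age by offsetting with the landmark.

## Excess-hazard regression

The additive model `λ_obs,i(t) = λ_pop,i(t) + λ0(t)·exp(β′x_i)` is fitted
by full maximum likelihood jointly in `(β, log λ0)` with a
piecewise-constant baseline (Estève formulation); Newton–Raphson with
analytic gradient/Hessian and step-halving, so the log-likelihood ascends
monotonically. Windows follow the reporting convention: 0–2 y on all
patients (breaks {0, 0.5, 1, 2}), 2–10 y on the 2-year landmark OS
population (breaks {2, 4, 6, 10}), 5–10 y on the 5-year landmark OS
population (breaks {5, 7, 10}); subjects event-free past the window end are
administratively censored there, so disjoint windows partition person-time.
The event is death from any cause — the population hazard absorbs the
background, the Cox part models the excess. Covariates are coded on the
conventional scales (age per decade, year of transplant per 5 years;
baselines male / MDS without excess blasts / HLA-identical sibling /
myeloablative; missing conditioning kept as its own level). Convergence is
declared at gradient max-norm below `max(1e−8, 1e−12·events)` (the gradient
is a sum over events, so its floating-point noise floor scales with the
event count) or a vanishing Newton step. Cause-specific Cox models use the
partial likelihood with Efron ties; ties never arise in the continuous-time
full likelihood.

Degenerate situations are flagged rather than hidden: monotone partial
likelihoods (separation) set a flag with infinite-SE markers; a baseline
segment collapsing to zero while it still contains deaths with zero
population hazard aborts with an unbounded-likelihood error.

## The synthetic registry and its calibration

Real registry data of this kind are not redistributable, so the package
ships a fully specified generator whose implied marginal curves are
calibrated to the published summaries of a large European MDS/sAML cohort
(6,434 adults, 2000–2012, database closure December 2016).

**What the generator emulates.** Covariate frequencies of the published
baseline table (sex 59/41, age bands 21/25/41/13 with ages 18–76 and
median 56, subtype 21/42/37, donor 41/59, conditioning 43/55/2, entry-year
periods normalised from the printed percentages); one synthetic
Gompertz–Makeham life table per sex shared by the eight listed
countries/regions, with levels close to pooled western-European period
tables of the 2000s (male q ≈ 0.0017 at 40, 0.024 at 70; female ≈ 0.6× the
level) and no secular trend; piecewise-constant baseline hazards with
multiplicative covariate effects for relapse (breaks {0, 0.5, 1, 2, 5,
10} y), excess NRM (same breaks), and post-relapse death (breaks {0, 0.25,
0.5, 1, 2} y on the since-relapse clock); population death times drawn by
exact inversion of each subject's matched cumulative hazard;
loss-to-follow-up at 0.035/y plus administrative censoring at closure.
Each subject has a dedicated counter-keyed random substream
(`SeedSequence([seed, i])`), so enlarging a cohort never reshuffles
earlier subjects.

**The analytic oracle.** The same generating law is integrated
deterministically: per covariate stratum (integer age × sex × subtype; 354
strata) the Kolmogorov forward equations of the EF phase are solved exactly
for step hazards (cell-exact exponential propagation, step 0.005 y), and
death after relapse — semi-Markov, hence a double integral over relapse
time — is evaluated with two-point Gauss quadrature inside each relapse
cell. Halving the step changes results by < 1e−6. Simulator and oracle are
held together by agreement tests at n = 100,000.

**Calibration** is deterministic root-finding of scenario parameters
against oracle-implied summaries, in two square stages:

1. *Event-free stage* (12 parameters / 12 targets): early and late scales
   of the relapse and excess baselines, late shape factors, and per-band
   late log-hazard-ratios, solved against whole-cohort EFS/CIR at 2 and
   10 y, NRM at 2 y, and the published 5-year post-landmark CIR and NRM of
   the four age bands among 2-year event-free survivors.
2. *Post-relapse stage* (3 parameters / 3 targets): the early, mid and
   late post-relapse baseline scales against the median survival after
   relapse (4.6 months), the 2-year post-relapse survival (19%), and the
   10-year overall survival (35%), which pins the long-term survival of
   early relapses.

All residuals are below 0.2 percentage points (2% relative for the
median); the calibration report is printed by `latemort calibrate`.

**Design constants chosen where the published summaries leave freedom.**
The within-block hazard shapes are fixed, not calibrated: excess NRM is
front-loaded (ratios 1 / 0.6 / 0.35 over the first three segments —
transplant toxicity concentrates early), while the relapse hazard is flat
over the first two years. Post-relapse mortality beyond two years since
transplant is attenuated by a factor 0.20: survivors of early relapse and
late relapses both carry a much lower excess risk than fresh early
relapses. Jointly these encode two further published observations that the
marginal post-relapse curve alone cannot fix: the one-year mortality of
2-year survivors with versus without previous relapse (34% vs 6%) and,
through it, the previous-relapse hazard ratio of about 5 in the 2–10-year
excess model, as well as the 5-year landmark survival of the oldest band
(63%). A homogeneous post-relapse hazard matching the marginal curve
cannot reproduce that contrast, which is the quantitative fingerprint of
heterogeneous relapse aggressiveness. The generator also supports an
explicit two-point frailty on the post-relapse transition
(fulminant/indolent classes, integrated exactly in the oracle); scenario
`ebmt2018` leaves it disabled, because with the marginal curve recalibrated
the frailty adds nothing that the timing structure does not already
provide — the capability remains for sensitivity studies.

**What the generator does not emulate.** Joint covariate dependence beyond
the published marginals (e.g. the real age–subtype association); country-
or centre-level heterogeneity; secular trends (no year effects on hazards
or tables, so fitted year-of-transplant hazard ratios are null by design);
cause-of-death taxonomies; the registry's two-layer censoring (disease
assessment vs vital status) — a single last-follow-up time is carried.
Passing tests therefore show that the estimators recover the truth of a
realistic, calibrated generating law, not that they are robust to every
feature of real registry data.

## Numerical choices and conventions

* Ties: events precede censorings at identical times (censored subjects
  remain in the risk set of that time).
* Confidence intervals: log(−log) transform for survival curves and CIFs
  (bounds stay in [0, 1]); Aalen delta-method CIF variances
  (Klein–Moeschberger form); 95% Wald intervals for regression.
* Median survival: smallest grid time with S ≤ 0.5; interval from where
  the confidence bands cross 0.5; flagged undefined when no crossing.
* Completeness index: potential follow-up ends at death or dataset closure
  (2017.0), whichever is first; index 1 when the potential time is zero;
  records with observed follow-up exceeding potential are rejected.
* Risk-set computations group subjects sharing a matched-hazard trajectory
  (identical integer age, sex, country — and entry year only when the
  table has a secular trend), which keeps the decomposition O(groups ×
  grid) instead of O(n × grid).
* Degenerate inputs: all-censored Kaplan–Meier returns the unit curve with
  a flag; an emptied risk set truncates the increment grid with a flag;
  empty landmark populations are explicit empty results, not exceptions.

## Problem sizes

The acceptance script simulates n = 100,000 (whole-cohort and landmark
estimates) and n = 50,000 (regression) — large enough that Monte-Carlo
error is small against every reported tolerance, and comfortably a
one-minute run on one CPU. The test suite uses n between 2,000 and 100,000
depending on the precision a check needs, 50 replicates of n = 10,000 for
the null-excess calibration check, and 20 replicates of n = 20,000 for
coefficient consistency and Wald coverage.

## Known limitations

* The expected-survival and decomposition estimators are Ederer II-style
  (risk-set conditioned); no Ederer I / Hakulinen variants.
* The excess model's baseline is piecewise-constant; no splines or
  time-varying coefficients, and no frailty/centre effects.
* The completeness index reports cohort-level summaries only (the record
  schema carries no centre identifier).
* Life tables are deterministic inputs; their sampling uncertainty (tiny
  for national tables) is ignored, as is conventional in relative
  survival.
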