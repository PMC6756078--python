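# latemort

**How much of the late mortality after an allogeneic stem-cell transplant is
actually caused by the transplant?**

Patients transplanted for myelodysplastic syndromes (MDS) or secondary AML
are increasingly old — a substantial fraction is over 65 at transplant. For
them, part of the "non-relapse mortality" (NRM) reported by registries is
mortality they would have faced anyway as members of the general population.
`latemort` implements the relative-survival decomposition that separates the
two, aimed at biostatisticians analysing registry cohorts of transplant (or
other cancer) survivors:

* **Nonparametric estimation** — Kaplan–Meier with Greenwood variance and
  log(−log) intervals, Aalen–Johansen cumulative incidences for the
  competing first events (relapse/progression vs NRM), landmark populations
  with clock reset, the unweighted log-rank test, and the
  completeness-of-follow-up index (observed / potential person-time).
* **Matched population hazards** — HMD-style period life tables (a reader
  for the 1×1 text dialect plus a Gompertz–Makeham synthetic builder),
  exact piecewise-constant integration along the Lexis diagonal
  (`h = −ln(1−q)` within each age × calendar-year cell), and Ederer II
  expected survival.
* **The decomposition** — on the grid of observed times, the NRM hazard
  increment splits as

      dΛ_nrm(t) = dΛ_pop(t) + dΛ_excess(t),

  where `dΛ_pop` is the matched life-table hazard averaged over the current
  event-free risk set. Product-integration through the five-state
  illness–death structure (event-free → relapse → death after relapse;
  event-free → population death | excess death) yields stacked state-occupation
  probabilities; the excess component is the model-based estimate of
  treatment-related mortality (TRM). Negative increments are retained so
  that population + excess equals the Aalen–Johansen NRM incidence exactly.
* **Excess-hazard regression** — the additive model of relative survival,

      λ_obs,i(t) = λ_pop,i(t) + λ0(t) · exp(β′x_i),

  fitted by full maximum likelihood with a piecewise-constant baseline
  (Estève formulation) on defined time windows and landmark populations,
  plus ordinary cause-specific Cox models (Efron ties) for comparison.
* **A calibrated synthetic registry** — scenario `ebmt2018` emulates a
  European adult MDS/sAML transplant cohort (2000–2012 accrual, closure end
  of 2016): covariate frequencies from the published baseline table, Cox-form
  covariate effects on every transition, exact inversion sampling of matched
  population death times, and deterministic calibration of the baseline
  hazards (root-finding against the model's own Kolmogorov forward
  equations) so that the implied marginal curves reproduce the published
  survival summaries. The same forward equations serve as the analytic
  oracle in the test suite.

## Worked example

```python
import numpy as np
from latemort import *
from latemort.cohort import s1_lifetables, s1_scenario, sample_cohort
from latemort.survival import os_times, competing_risk_codes

tables = s1_lifetables()
scenario, report = s1_scenario()          # deterministic calibration
cohort = sample_cohort(scenario, tables, 20_000, seed=1)

t, e = os_times(cohort.data)
km = kaplan_meier(t, e)
print(f"OS at 2y:  {100 * km.at(2):.1f}%")
print(f"OS at 10y: {100 * km.at(10):.1f}%")

t, c = competing_risk_codes(cohort.data)
aj = aalen_johansen(t, c)
print(f"CIR at 2y: {100 * aj.at(1, 2):.1f}%   NRM at 2y: {100 * aj.at(2, 2):.1f}%")

lm = make_landmark(cohort, 2.0, "EF")     # event-free at 2 years
old = lm.data[lm.data.age >= 65].reset_index(drop=True)
sub = LandmarkCohort(old, 2.0, "EF", lm.closure, lm.n_parent)
stack = stacked_state_probabilities(split_nrm_increments(sub, tables))
pop = stack.component_at("P_nrm_pop", 5.0)
exc = stack.component_at("P_nrm_excess", 5.0)
print(f">=65 at HCT, event-free at 2y (n={len(old)}):")
print(f"  5y population mortality: {100*pop:.1f}%")
print(f"  5y excess (treatment-related) mortality: {100*exc:.1f}%")
print(f"  population share of NRM: {100*pop/(pop+exc):.0f}%")
```

Output:

```
OS at 2y:  52.1%
OS at 10y: 34.8%
CIR at 2y: 27.2%   NRM at 2y: 26.4%
>=65 at HCT, event-free at 2y (n=1037):
  5y population mortality: 7.5%
  5y excess (treatment-related) mortality: 17.1%
  population share of NRM: 30%
```

Reading: of the ~25% five-year NRM faced by patients transplanted at ≥65
who reach the two-year landmark event-free, roughly a third is ordinary
population mortality — the transplant-attributable part is ~17%, not 25%.
For patients under 45 the population share is well under a tenth.

The same analysis, end to end with all tables written to disk:

```bash
latemort analyze -n 20000 --seed 1 --out results/
latemort simulate -n 10000 --seed 1 --truth --out cohort.csv   # raw cohort
latemort calibrate                                             # calibration report
```

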