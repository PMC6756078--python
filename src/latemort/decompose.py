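"""Splitting non-relapse mortality into population and excess components.

The central quantity of the analysis: on the grid of observed times the
cause-specific hazard increment of NRM is decomposed as

    dL_nrm(t) = dL_pop(t) + dL_excess(t),

where ``dL_pop`` is the matched life-table hazard averaged over the
current event-free risk set (the Ederer II convention, conditioning on
the observed censoring pattern) and ``dL_excess`` is the remainder —
interpreted as treatment-related mortality.  Product-integrating these
increments through the five-state structure (event-free, alive after
relapse, death after relapse, population NRM, excess NRM) yields the
stacked state probabilities of the outcome decomposition.

Excess increments may be negative on intervals where fewer deaths are
observed than the population tables predict; they are deliberately not
floored at zero, which preserves the exact identity

    P_NRM_pop(t) + P_NRM_excess(t) = Aalen-Johansen CIF_NRM(t)

on the same grid.  Only displayed probabilities are clipped to [0, 1].

Post-relapse population mortality is computed and carried internally
but merged into death-after-relapse for reporting: the prognosis after
relapse is so poor that its population component is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .lifetables import ClampCounter, LifeTableCollection, MatchProfile
from .survival import LandmarkCohort

__all__ = [
    "HazardIncrements",
    "StackedProbabilities",
    "split_nrm_increments",
    "stacked_state_probabilities",
    "population_share_of_nrm",
    "bootstrap_stacked",
]


@dataclass
class HazardIncrements:
    """Cause-specific hazard increments on the observed time grid.

    Grid times are the pooled observed exit times (events and
    censorings, so the population-hazard integrals track the risk set
    closely).  ``dL_excess_ef = dL_nrm - dL_pop_ef`` by construction and
    may be negative.  ``truncated_at`` is set when the event-free risk
    set empties before the last observed time.
    """

    time: np.ndarray
    dL_relapse: np.ndarray
    dL_nrm: np.ndarray
    dL_pop_ef: np.ndarray
    dL_excess_ef: np.ndarray
    dL_death_after_relapse: np.ndarray
    dL_pop_r: np.ndarray
    Y_ef: np.ndarray
    Y_r: np.ndarray
    truncated_at: float | None = None
    clamping: ClampCounter = field(default_factory=ClampCounter)


def _pop_interp_groups(
    data: pd.DataFrame,
    tables: LifeTableCollection,
    horizon: float,
    counter: ClampCounter,
):
    """Group subjects sharing a matched-hazard trajectory.

    Registry cohorts contain many subjects with identical integer entry
    age, sex and country, so the per-group cumulative-hazard
    interpolators are shared.  Returns (group index per subject, list of
    (knots, cum) per group).
    """
    countries = data["country"].to_numpy()
    sexes = data["sex"].to_numpy()
    ages = np.round(data["age"].to_numpy(dtype=float), 9)
    years = np.round(data["year_hct"].to_numpy(dtype=float), 9)
    # entry year only distinguishes trajectories when the table has a
    # secular trend; with year-invariant tables it would make every
    # subject its own group
    inv_cache: dict[tuple[str, str], bool] = {}

    def year_key(country, sex, year):
        k = (country, sex)
        inv = inv_cache.get(k)
        if inv is None:
            inv = tables.get(country, sex).year_invariant
            inv_cache[k] = inv
        return None if inv else year

    group_of: dict = {}
    gidx = np.empty(len(countries), dtype=int)
    interps = []
    for i in range(len(countries)):
        key = (countries[i], sexes[i], ages[i], year_key(countries[i], sexes[i], years[i]))
        g = group_of.get(key)
        if g is None:
            g = len(interps)
            group_of[key] = g
            prof = MatchProfile(ages[i], sexes[i], countries[i], years[i])
            interps.append(tables.cum_hazard_interp(prof, horizon, counter))
        gidx[i] = g
    return gidx, interps


def split_nrm_increments(
    cohort: Cohort | LandmarkCohort,
    tables: LifeTableCollection,
) -> HazardIncrements:
    """Decompose observed NRM hazard increments into population + excess.

    Works on a whole cohort (clock = time since HCT) or a landmark
    population (clock = time since landmark; the matched population
    hazard is evaluated at the correct attained age and calendar time
    by offsetting with the landmark).
    """
    data = cohort.data
    if len(data) == 0:
        raise ValueError("empty cohort")
    offset = getattr(cohort, "landmark", 0.0)
    counter = ClampCounter()

    rel = data["t_relapse"].to_numpy(dtype=float)
    dth = data["t_death"].to_numpy(dtype=float)
    last = data["t_last_fu"].to_numpy(dtype=float)
    relapsed = ~np.isnan(rel)
    dead = ~np.isnan(dth)

    # event-free phase exit: first of relapse, death, censoring
    ef_exit = np.where(relapsed, rel, np.where(dead, dth, last))
    ef_event_rel = relapsed
    ef_event_nrm = dead & ~relapsed
    # post-relapse phase: entry at relapse, exit at death or censoring
    r_entry = rel[relapsed]
    r_exit = np.where(dead[relapsed], dth[relapsed], last[relapsed])
    r_event = dead[relapsed]

    grid = np.unique(np.concatenate([ef_exit, r_exit if r_exit.size else np.empty(0)]))
    grid = grid[grid > 0]
    if grid.size == 0:
        raise ValueError("no positive follow-up times")

    horizon = offset + float(grid[-1]) + 1.0
    gidx, interps = _pop_interp_groups(data, tables, horizon, counter)
    n_groups = len(interps)
    abs_grid = offset + np.concatenate([[0.0], grid])

    def risk_weighted_pop(exit_times, groups, strict_entry=None):
        """Per-interval sums over the risk set: count and matched
        cumulative-hazard increment, streamed per trajectory group.

        At risk at grid time t_j: exit >= t_j (and entry < t_j when
        ``strict_entry`` is given, for the post-relapse state).
        """
        Y = np.zeros(len(grid))
        pop = np.zeros(len(grid))
        order = np.argsort(groups, kind="stable")
        sorted_groups = groups[order]
        bounds = np.searchsorted(sorted_groups, np.arange(n_groups + 1))
        for g in range(n_groups):
            sel = order[bounds[g]:bounds[g + 1]]
            if sel.size == 0:
                continue
            ex = np.sort(exit_times[sel])
            cnt = len(ex) - np.searchsorted(ex, grid - 1e-12, side="left")
            if strict_entry is not None:
                # at risk requires entry strictly before t_j: remove the
                # not-yet-entered (entry >= t_j), all of whom also have
                # exit >= t_j
                en = np.sort(strict_entry[sel])
                cnt = cnt - (len(en) - np.searchsorted(en, grid - 1e-12, side="left"))
            knots, cum = interps[g]
            dHg = np.diff(np.interp(abs_grid, knots, cum))
            Y += cnt
            pop += cnt * dHg
        return Y, pop

    Y_ef, pop_sum_ef = risk_weighted_pop(ef_exit, gidx)

    if r_entry.size:
        Y_r, pop_sum_r = risk_weighted_pop(r_exit, gidx[relapsed], strict_entry=r_entry)
    else:
        Y_r = np.zeros(len(grid))
        pop_sum_r = np.zeros(len(grid))

    def event_counts(times):
        ts = np.sort(times)
        return (
            np.searchsorted(ts, grid, side="right")
            - np.searchsorted(ts, grid, side="left")
        ).astype(float)

    d_rel = event_counts(ef_exit[ef_event_rel])
    d_nrm = event_counts(ef_exit[ef_event_nrm])
    d_rd = event_counts(r_exit[r_event]) if r_entry.size else np.zeros(len(grid))

    truncated_at = None
    ok_ef = Y_ef > 0
    if not ok_ef.all():
        first = int(np.argmax(~ok_ef))
        truncated_at = float(grid[first])
        keep = np.arange(len(grid)) < first
    else:
        keep = np.ones(len(grid), dtype=bool)

    with np.errstate(divide="ignore", invalid="ignore"):
        dL_rel = np.where(Y_ef > 0, d_rel / Y_ef, 0.0)
        dL_nrm = np.where(Y_ef > 0, d_nrm / Y_ef, 0.0)
        dL_pop = np.where(Y_ef > 0, pop_sum_ef / Y_ef, 0.0)
        dL_rd = np.where(Y_r > 0, d_rd / Y_r, 0.0)
        dL_pop_r = np.where(Y_r > 0, pop_sum_r / Y_r, 0.0)

    return HazardIncrements(
        time=grid[keep],
        dL_relapse=dL_rel[keep],
        dL_nrm=dL_nrm[keep],
        dL_pop_ef=dL_pop[keep],
        dL_excess_ef=(dL_nrm - dL_pop)[keep],
        dL_death_after_relapse=dL_rd[keep],
        dL_pop_r=dL_pop_r[keep],
        Y_ef=Y_ef[keep],
        Y_r=Y_r[keep],
        truncated_at=truncated_at,
        clamping=counter,
    )


@dataclass
class StackedProbabilities:
    """State-occupation probabilities of the five-way decomposition.

    At every grid time the five components sum to one:
    event-free, alive after relapse, death after relapse (population
    and excess pathways merged), population NRM, excess NRM (= TRM).
    Arrays are kept un-clipped so the decomposition identity holds
    exactly; ``to_frame`` clips to [0, 1] for display.
    """

    time: np.ndarray
    P_ef: np.ndarray
    P_alive_after_relapse: np.ndarray
    P_death_after_relapse: np.ndarray
    P_nrm_pop: np.ndarray
    P_nrm_excess: np.ndarray
    lower: dict[str, np.ndarray] | None = None
    upper: dict[str, np.ndarray] | None = None

    _STATES = (
        "P_ef", "P_alive_after_relapse", "P_death_after_relapse",
        "P_nrm_pop", "P_nrm_excess",
    )

    def component_at(self, name: str, t: float) -> float:
        arr = getattr(self, name)
        i = int(np.searchsorted(self.time, t, side="right")) - 1
        if i < 0:
            return 1.0 if name == "P_ef" else 0.0
        return float(arr[i])

    def total(self) -> np.ndarray:
        return sum(getattr(self, s) for s in self._STATES)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for s in self._STATES:
            est = np.clip(getattr(self, s), 0.0, 1.0)
            f = pd.DataFrame({"time": self.time, "state": s, "probability": est})
            if self.lower is not None:
                f["lower"] = self.lower[s]
                f["upper"] = self.upper[s]
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def stacked_state_probabilities(inc: HazardIncrements) -> StackedProbabilities:
    """Product-integrate hazard increments into stacked probabilities.

    Recursive scheme per grid step: the event-free state loses mass to
    relapse, population NRM and excess NRM; the relapse state gains the
    relapse inflow and loses deaths after relapse (population and
    excess pathways merged).  The five components sum to one by
    construction.
    """
    m = len(inc.time)
    P_ef = np.empty(m + 1)
    P_r = np.empty(m + 1)
    P_dar = np.empty(m + 1)
    P_pop = np.empty(m + 1)
    P_exc = np.empty(m + 1)
    P_ef[0], P_r[0], P_dar[0], P_pop[0], P_exc[0] = 1.0, 0.0, 0.0, 0.0, 0.0
    for j in range(m):
        ef_prev = P_ef[j]
        r_prev = P_r[j]
        out_ef = inc.dL_relapse[j] + inc.dL_pop_ef[j] + inc.dL_excess_ef[j]
        P_ef[j + 1] = ef_prev * (1.0 - out_ef)
        if P_ef[j + 1] < -1e-8:
            raise ValueError(
                "event-free occupation probability driven below zero at "
                f"t={inc.time[j]:.4f} (pathological negative excess); "
                "use a coarser grid"
            )
        P_pop[j + 1] = P_pop[j] + ef_prev * inc.dL_pop_ef[j]
        P_exc[j + 1] = P_exc[j] + ef_prev * inc.dL_excess_ef[j]
        P_r[j + 1] = r_prev * (1.0 - inc.dL_death_after_relapse[j]) + ef_prev * inc.dL_relapse[j]
        P_dar[j + 1] = P_dar[j] + r_prev * inc.dL_death_after_relapse[j]
    return StackedProbabilities(
        time=inc.time,
        P_ef=P_ef[1:],
        P_alive_after_relapse=P_r[1:],
        P_death_after_relapse=P_dar[1:],
        P_nrm_pop=P_pop[1:],
        P_nrm_excess=P_exc[1:],
    )


def population_share_of_nrm(stacked: StackedProbabilities, t: float) -> float:
    """Fraction of NRM at time ``t`` attributable to population mortality.

    Returns NaN (flagged undefined) when no NRM has accumulated by ``t``.
    """
    pop = stacked.component_at("P_nrm_pop", t)
    exc = stacked.component_at("P_nrm_excess", t)
    denom = pop + exc
    if denom <= 0:
        return np.nan
    return pop / denom


def bootstrap_stacked(
    cohort: Cohort | LandmarkCohort,
    tables: LifeTableCollection,
    times: Sequence[float],
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[StackedProbabilities, pd.DataFrame]:
    """Stacked probabilities with nonparametric bootstrap 95% intervals.

    Subjects are resampled with replacement ``n_boot`` times; intervals
    are percentile-based, evaluated at ``times``.  Returns the point
    estimate (full grid) and a tidy frame of intervals.
    """
    times = np.asarray(times, dtype=float)
    point = stacked_state_probabilities(split_nrm_increments(cohort, tables))
    rng = np.random.default_rng(seed)
    n = len(cohort.data)
    samples = {s: np.empty((n_boot, len(times))) for s in StackedProbabilities._STATES}
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boot_data = cohort.data.iloc[idx].reset_index(drop=True)
        if isinstance(cohort, LandmarkCohort):
            boot = LandmarkCohort(
                data=boot_data, landmark=cohort.landmark, kind=cohort.kind,
                closure=cohort.closure, n_parent=cohort.n_parent,
            )
        else:
            boot = Cohort(data=boot_data, closure=cohort.closure)
        st = stacked_state_probabilities(split_nrm_increments(boot, tables))
        for s in StackedProbabilities._STATES:
            for ti, t in enumerate(times):
                samples[s][b, ti] = st.component_at(s, t)
    rows = []
    for s in StackedProbabilities._STATES:
        lo = np.percentile(samples[s], 2.5, axis=0)
        hi = np.percentile(samples[s], 97.5, axis=0)
        for ti, t in enumerate(times):
            rows.append(
                {
                    "time": t, "state": s,
                    "probability": point.component_at(s, t),
                    "lower": lo[ti], "upper": hi[ti],
                }
            )
    return point, pd.DataFrame(rows)
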