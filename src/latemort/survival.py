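"""Nonparametric survival estimation.

Kaplan–Meier curves with Greenwood variance and log–log confidence
intervals, Aalen–Johansen cumulative incidences for competing risks,
landmark population construction (with clock reset), the unweighted
log-rank test, and the completeness-of-follow-up index (ratio of
observed to potential person-time, used to audit registry reporting
quality).

Tie convention throughout: events precede censorings at identical
times, i.e. subjects censored at an event time are still counted in the
risk set of that event time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

__all__ = [
    "SurvivalCurve",
    "CIFSet",
    "LandmarkCohort",
    "MedianEstimate",
    "CompletenessIndex",
    "kaplan_meier",
    "aalen_johansen",
    "make_landmark",
    "median_from_curve",
    "logrank_test",
    "clark_completeness",
    "os_times",
    "efs_times",
    "competing_risk_codes",
]

_Z95 = 1.959963984540054


def _validate_times(times, events=None):
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if np.any(times < 0) or np.any(~np.isfinite(times)):
        raise ValueError("times must be finite and non-negative")
    if events is None:
        return times
    events = np.asarray(events)
    if events.shape != times.shape:
        raise ValueError("times and events must have equal length")
    return times, events


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Product-limit estimate on the grid of observed event times.

    ``survival[j]`` is the estimate at ``time[j]`` (right-continuous
    step function); before the first event time the estimate is 1.
    ``lower``/``upper`` are pointwise 95% limits on the log(-log)
    scale, which keeps them inside [0, 1].
    """

    time: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    n_at_entry: int
    no_events: bool = False

    def at(self, t: float) -> float:
        i = int(np.searchsorted(self.time, t, side="right")) - 1
        return 1.0 if i < 0 else float(self.survival[i])

    def ci_at(self, t: float) -> tuple[float, float]:
        i = int(np.searchsorted(self.time, t, side="right")) - 1
        if i < 0:
            return (1.0, 1.0)
        return float(self.lower[i]), float(self.upper[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "estimate": self.survival,
                "lower": self.lower,
                "upper": self.upper,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
            }
        )


def _loglog_ci(surv: np.ndarray, var: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lower = np.empty_like(surv)
    upper = np.empty_like(surv)
    interior = (surv > 0) & (surv < 1) & (var > 0)
    s = surv[interior]
    se_theta = np.sqrt(var[interior]) / (s * np.abs(np.log(s)))
    theta = np.log(-np.log(s))
    lower[interior] = np.exp(-np.exp(theta + _Z95 * se_theta))
    upper[interior] = np.exp(-np.exp(theta - _Z95 * se_theta))
    lower[~interior] = surv[~interior]
    upper[~interior] = surv[~interior]
    return lower, upper


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan–Meier estimate with Greenwood variance and log–log 95% CI.

    ``events`` is 1 for an observed event, 0 for right-censoring.  An
    all-censored input returns the constant curve 1 flagged with
    ``no_events``.
    """
    times, events = _validate_times(times, events)
    events = events.astype(bool)
    n = len(times)
    if not events.any():
        t = np.array([times.max()])
        one = np.ones(1)
        return SurvivalCurve(
            time=t, survival=one, variance=np.zeros(1), lower=one, upper=one,
            n_risk=np.array([n]), n_event=np.zeros(1, dtype=int),
            n_at_entry=n, no_events=True,
        )
    t_ev = np.unique(times[events])
    # risk set: time >= t (censored at t still at risk at t)
    order = np.sort(times)
    n_risk = n - np.searchsorted(order, t_ev, side="left")
    ev_sorted = np.sort(times[events])
    n_event = (
        np.searchsorted(ev_sorted, t_ev, side="right")
        - np.searchsorted(ev_sorted, t_ev, side="left")
    )
    frac = 1.0 - n_event / n_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = n_event / (n_risk * (n_risk - n_event))
    gw_terms[~np.isfinite(gw_terms)] = 0.0
    var = surv**2 * np.cumsum(gw_terms)
    lower, upper = _loglog_ci(surv, var)
    return SurvivalCurve(
        time=t_ev, survival=surv, variance=var, lower=lower, upper=upper,
        n_risk=n_risk, n_event=n_event, n_at_entry=n,
    )


# ---------------------------------------------------------------------------
# Aalen-Johansen competing risks
# ---------------------------------------------------------------------------

@dataclass
class CIFSet:
    """Aalen–Johansen cumulative incidence functions for competing causes.

    ``cif[k]`` is cause ``k``'s cumulative incidence at the pooled event
    times; ``overall_survival`` is the all-cause Kaplan–Meier on the
    same grid, so ``overall_survival + sum_k cif[k] = 1`` at every time.
    Variances are the Aalen delta-method estimates; intervals use the
    log(-log) transform.
    """

    time: np.ndarray
    cif: dict[int, np.ndarray]
    variance: dict[int, np.ndarray]
    lower: dict[int, np.ndarray]
    upper: dict[int, np.ndarray]
    n_risk: np.ndarray
    n_event: dict[int, np.ndarray]
    overall_survival: np.ndarray
    n_at_entry: int = 0

    @property
    def causes(self) -> list[int]:
        return sorted(self.cif)

    def at(self, cause: int, t: float) -> float:
        i = int(np.searchsorted(self.time, t, side="right")) - 1
        return 0.0 if i < 0 else float(self.cif[cause][i])

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for k in self.causes:
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.time,
                        "cause": k,
                        "estimate": self.cif[k],
                        "lower": self.lower[k],
                        "upper": self.upper[k],
                        "n_risk": self.n_risk,
                        "n_event": self.n_event[k],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def aalen_johansen(times: Sequence[float], causes: Sequence[int]) -> CIFSet:
    """Aalen–Johansen cumulative incidences.

    ``causes``: 0 for censoring, positive integers for competing event
    types (1 relapse/progression, 2 non-relapse mortality in the main
    analyses).  ``CIF_k(t) = sum over event times t_j <= t of
    S(t_j-) d_kj / n_j`` with ``S`` the all-cause Kaplan–Meier.
    """
    times, causes = _validate_times(times, causes)
    causes = causes.astype(int)
    if np.any(causes < 0):
        raise ValueError("cause codes must be >= 0 (0 = censored)")
    cause_ids = sorted(set(causes[causes > 0]))
    n = len(times)
    any_event = causes > 0
    if not any_event.any():
        t = np.array([times.max()])
        z = np.zeros(1)
        return CIFSet(
            time=t, cif={1: z.copy(), 2: z.copy()},
            variance={1: z.copy(), 2: z.copy()},
            lower={1: z.copy(), 2: z.copy()}, upper={1: z.copy(), 2: z.copy()},
            n_risk=np.array([n]), n_event={1: z.copy(), 2: z.copy()},
            overall_survival=np.ones(1), n_at_entry=n,
        )
    t_ev = np.unique(times[any_event])
    order = np.sort(times)
    n_risk = n - np.searchsorted(order, t_ev, side="left")
    d_all = np.zeros(len(t_ev))
    d_k = {}
    for k in cause_ids:
        ts = np.sort(times[causes == k])
        d = (
            np.searchsorted(ts, t_ev, side="right")
            - np.searchsorted(ts, t_ev, side="left")
        ).astype(float)
        d_k[k] = d
        d_all += d
    surv = np.cumprod(1.0 - d_all / n_risk)
    s_minus = np.concatenate([[1.0], surv[:-1]])
    cif = {k: np.cumsum(s_minus * d_k[k] / n_risk) for k in cause_ids}
    # Aalen delta-method variance (Klein & Moeschberger form)
    variance = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = d_all / (n_risk * (n_risk - d_all))
    gw[~np.isfinite(gw)] = 0.0
    for k in cause_ids:
        Fk = cif[k]
        dk = d_k[k]
        # terms evaluated at each horizon t via cumulative sums
        a = np.cumsum(gw)                    # sum d/(n(n-d))
        b = np.cumsum(Fk * gw)
        c = np.cumsum(Fk**2 * gw)
        e = np.cumsum(s_minus**2 * (n_risk - dk) * dk / n_risk**3)
        f = np.cumsum(s_minus * dk / n_risk**2)
        g = np.cumsum(Fk * s_minus * dk / n_risk**2)
        var = (Fk**2 * a - 2 * Fk * b + c) + e - 2 * (Fk * f - g)
        variance[k] = np.maximum(var, 0.0)
    lower, upper = {}, {}
    for k in cause_ids:
        lo, up = _cif_loglog_ci(cif[k], variance[k])
        lower[k], upper[k] = lo, up
    return CIFSet(
        time=t_ev, cif=cif, variance=variance, lower=lower, upper=upper,
        n_risk=n_risk, n_event=d_k, overall_survival=surv, n_at_entry=n,
    )


def _cif_loglog_ci(F: np.ndarray, var: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lower = F.copy()
    upper = F.copy()
    interior = (F > 0) & (F < 1) & (var > 0)
    f = F[interior]
    se_theta = np.sqrt(var[interior]) / (f * np.abs(np.log(f)))
    theta = np.log(-np.log(f))
    lower[interior] = np.exp(-np.exp(theta + _Z95 * se_theta))
    upper[interior] = np.exp(-np.exp(theta - _Z95 * se_theta))
    return lower, upper


# ---------------------------------------------------------------------------
# endpoint extraction from cohorts
# ---------------------------------------------------------------------------

def os_times(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(time, event) for overall survival: death from any cause."""
    dead = data["t_death"].notna().to_numpy()
    t = np.where(dead, data["t_death"].to_numpy(), data["t_last_fu"].to_numpy())
    return t, dead.astype(int)


def efs_times(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(time, event) for event-free survival: first of relapse or death."""
    rel = data["t_relapse"].to_numpy(dtype=float)
    dth = data["t_death"].to_numpy(dtype=float)
    first = np.fmin(np.where(np.isnan(rel), np.inf, rel),
                    np.where(np.isnan(dth), np.inf, dth))
    ev = np.isfinite(first)
    t = np.where(ev, first, data["t_last_fu"].to_numpy())
    return t, ev.astype(int)


def competing_risk_codes(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(time, cause) with 1 = relapse/progression, 2 = NRM, 0 = censored."""
    rel = data["t_relapse"].to_numpy(dtype=float)
    dth = data["t_death"].to_numpy(dtype=float)
    relapsed = ~np.isnan(rel)
    died_ef = ~np.isnan(dth) & ~relapsed
    t = np.where(relapsed, rel, np.where(died_ef, dth, data["t_last_fu"].to_numpy()))
    cause = np.where(relapsed, 1, np.where(died_ef, 2, 0))
    return t, cause


# ---------------------------------------------------------------------------
# landmarking
# ---------------------------------------------------------------------------

@dataclass
class LandmarkCohort:
    """Patients alive (OS kind) or alive event-free (EF kind) at ``landmark``.

    Event times in ``data`` are reset to the post-landmark clock.  The
    OS population carries the binary covariate ``previous_relapse``
    (relapse before the landmark).  ``age``/``year_hct`` remain the
    values at transplant; absolute follow-up time since HCT is
    ``landmark`` plus the reset time, which matters when matching to
    life tables.
    """

    data: pd.DataFrame
    landmark: float
    kind: str
    closure: float
    n_parent: int

    def __len__(self) -> int:
        return len(self.data)

    @property
    def is_empty(self) -> bool:
        return len(self.data) == 0


def make_landmark(cohort: Cohort, L: float, kind: str) -> LandmarkCohort:
    """Construct the landmark analysis population at time ``L``.

    kind="OS": all patients alive and in follow-up at L (death after L,
    last follow-up >= L), with previous relapse carried as a covariate.
    kind="EF": additionally no relapse/progression before L.
    Subjects censored before L are excluded by definition.
    """
    if L <= 0:
        raise ValueError("landmark time must be positive")
    if kind not in ("OS", "EF"):
        raise ValueError("kind must be 'OS' or 'EF'")
    d = cohort.data
    alive = d["t_death"].isna() | (d["t_death"] > L)
    in_fu = d["t_last_fu"] >= L
    keep = alive & in_fu
    if kind == "EF":
        keep &= d["t_relapse"].isna() | (d["t_relapse"] > L)
    sub = d.loc[keep].copy()
    if kind == "OS":
        sub["previous_relapse"] = (
            sub["t_relapse"].notna() & (sub["t_relapse"] <= L)
        ).astype(int)
        # relapse before the landmark is a covariate, not a post-landmark event
        sub.loc[sub["previous_relapse"] == 1, "t_relapse"] = np.nan
    for col in ("t_relapse", "t_death"):
        sub[col] = sub[col] - L
    sub["t_last_fu"] = sub["t_last_fu"] - L
    return LandmarkCohort(
        data=sub.reset_index(drop=True),
        landmark=L, kind=kind, closure=cohort.closure, n_parent=len(d),
    )


# ---------------------------------------------------------------------------
# median survival
# ---------------------------------------------------------------------------

@dataclass
class MedianEstimate:
    time: float
    lower: float
    upper: float
    defined: bool = True


def median_from_curve(curve: SurvivalCurve) -> MedianEstimate:
    """Median survival: smallest grid time with S(t) <= 0.5.

    The 95% interval is read off where the pointwise confidence bands
    cross 0.5.  When the curve (or a band) never reaches 0.5 the
    corresponding value is NaN and ``defined`` is False for the point
    estimate.
    """

    def first_below(values: np.ndarray) -> float:
        idx = np.nonzero(values <= 0.5)[0]
        return float(curve.time[idx[0]]) if idx.size else np.nan

    med = first_below(curve.survival)
    # the lower confidence band crosses 0.5 first (earlier time)
    lo = first_below(curve.lower)
    up = first_below(curve.upper)
    return MedianEstimate(
        time=med, lower=lo, upper=up, defined=bool(np.isfinite(med))
    )


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence
) -> tuple[float, int, float]:
    """Unweighted log-rank test across two or more groups.

    Returns (chi-square statistic, degrees of freedom, p-value); the
    variance is the hypergeometric (conditional) variance at pooled
    event times.
    """
    times, events = _validate_times(times, events)
    events = events.astype(bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    gidx = np.searchsorted(labels, groups)
    G = len(labels)
    t_ev = np.unique(times[events])
    if t_ev.size == 0:
        return 0.0, G - 1, 1.0
    # per-group risk and event counts at each pooled event time
    n_risk = np.empty((G, len(t_ev)))
    d_obs = np.empty((G, len(t_ev)))
    for g in range(G):
        tg = np.sort(times[gidx == g])
        n_risk[g] = len(tg) - np.searchsorted(tg, t_ev, side="left")
        te = np.sort(times[(gidx == g) & events])
        d_obs[g] = np.searchsorted(te, t_ev, side="right") - np.searchsorted(
            te, t_ev, side="left"
        )
    N = n_risk.sum(axis=0)
    D = d_obs.sum(axis=0)
    E = n_risk * (D / N)[None, :]
    OmE = (d_obs - E).sum(axis=1)[:-1]
    # hypergeometric covariance of the first G-1 groups
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = D * (N - D) / (N - 1) / N**2
    factor[~np.isfinite(factor)] = 0.0
    V = np.zeros((G - 1, G - 1))
    for i in range(G - 1):
        for j in range(G - 1):
            if i == j:
                V[i, j] = np.sum(factor * n_risk[i] * (N - n_risk[i]))
            else:
                V[i, j] = -np.sum(factor * n_risk[i] * n_risk[j])
    try:
        chi2 = float(OmE @ np.linalg.solve(V, OmE))
    except np.linalg.LinAlgError:
        chi2 = float(OmE @ np.linalg.pinv(V) @ OmE)
    df = G - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


# ---------------------------------------------------------------------------
# completeness of follow-up (Clark's C-index)
# ---------------------------------------------------------------------------

@dataclass
class CompletenessIndex:
    """Observed / potential person-time of follow-up per subject.

    ``c`` is 1 for subjects who died or were followed to dataset
    closure; the cohort summaries mirror how registry reporting quality
    is usually described: the proportion with complete follow-up and
    the median/IQR of the index among the incompletely followed.
    """

    c: np.ndarray
    proportion_complete: float
    median_incomplete: float
    iqr_incomplete: tuple[float, float]
    n_incomplete: int = 0

    def summary(self) -> dict:
        return {
            "proportion_complete": self.proportion_complete,
            "median_c_incomplete": self.median_incomplete,
            "iqr_c_incomplete": list(self.iqr_incomplete),
            "n_incomplete": self.n_incomplete,
        }


def clark_completeness(
    cohort: Cohort, closure: float | None = None, tol: float = 1e-9
) -> CompletenessIndex:
    """Completeness-of-follow-up index of a cohort.

    Potential follow-up of subject i is ``min(death time, closure -
    entry)``; observed follow-up is the recorded last follow-up.  The
    index is their ratio (1 when the potential time is zero).  Records
    with observed follow-up exceeding the potential time are
    inconsistent and rejected.
    """
    if closure is None:
        closure = cohort.closure
    d = cohort.data
    entry = d["year_hct"].to_numpy(dtype=float)
    t_death = d["t_death"].to_numpy(dtype=float)
    t_last = d["t_last_fu"].to_numpy(dtype=float)
    potential = closure - entry
    dead = ~np.isnan(t_death)
    potential = np.where(dead, np.fmin(t_death, potential), potential)
    if np.any(t_last > potential + 1e-6):
        row = int(np.argmax(t_last > potential + 1e-6))
        raise ValueError(
            f"row {row}: observed follow-up {t_last[row]:.4f} exceeds "
            f"potential follow-up {potential[row]:.4f}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(potential <= tol, 1.0, np.clip(t_last / potential, 0.0, 1.0))
    complete = c >= 1 - 1e-9
    incomplete = c[~complete]
    if incomplete.size:
        med = float(np.median(incomplete))
        iqr = (float(np.percentile(incomplete, 25)), float(np.percentile(incomplete, 75)))
    else:
        med, iqr = np.nan, (np.nan, np.nan)
    return CompletenessIndex(
        c=c,
        proportion_complete=float(np.mean(complete)),
        median_incomplete=med,
        iqr_incomplete=iqr,
        n_incomplete=int((~complete).sum()),
    )
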