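"""Cox regression: cause-specific hazards and additive excess hazards.

Two regression models are used in the analysis:

* :func:`fit_cause_specific_cox` — an ordinary Cox proportional-hazards
  model for one cause-specific hazard (competing events censored),
  maximised by Newton–Raphson on the partial likelihood with Efron (or
  Breslow) handling of ties.

* :func:`fit_excess_cox` — the additive excess-hazard model of relative
  survival: the observed all-cause death hazard of subject *i* is

      lambda_obs,i(t) = lambda_pop,i(t) + lambda_0(t) * exp(beta' x_i),

  with ``lambda_pop`` the matched life-table hazard and a piecewise-
  constant baseline excess hazard ``lambda_0``.  The model is fitted by
  full maximum likelihood jointly over (beta, log lambda_0) — the
  piecewise-exponential (Esteve-type) formulation — within a defined
  time window, optionally on a landmark population.  When the
  population hazard is zero this degenerates to an ordinary
  proportional-hazards model for death.

Covariate coding follows the conventional reporting scales: age per
decade, calendar year of HCT per 5 years, and factor baselines male /
MDS without excess blasts / HLA-identical sibling / myeloablative
conditioning; missing conditioning is kept as its own category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .lifetables import ClampCounter, LifeTableCollection
from .survival import LandmarkCohort

__all__ = [
    "CoxFit",
    "ExcessCoxFit",
    "build_design",
    "fit_cause_specific_cox",
    "fit_excess_cox",
    "DEFAULT_COVARIATES",
]

_Z95 = 1.959963984540054

# covariate registry: name -> column builder
_COVARIATE_BUILDERS = {
    "female": lambda d: (d["sex"] == "female").astype(float),
    "age_decade": lambda d: d["age"].astype(float) / 10.0,
    "year_per5": lambda d: (d["year_hct"].astype(float) - 2000.0) / 5.0,
    "subtype_EB": lambda d: (d["subtype"] == "MDS_EB").astype(float),
    "subtype_sAML": lambda d: (d["subtype"] == "sAML").astype(float),
    "donor_other": lambda d: (d["donor"] == "other").astype(float),
    "cond_RIC": lambda d: (d["conditioning"] == "RIC").astype(float),
    "cond_missing": lambda d: (d["conditioning"] == "missing").astype(float),
    "previous_relapse": lambda d: d["previous_relapse"].astype(float),
}

DEFAULT_COVARIATES = [
    "female", "age_decade", "year_per5", "subtype_EB", "subtype_sAML",
    "donor_other", "cond_RIC", "cond_missing",
]


def build_design(data: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    """Design matrix on the conventional reporting scales."""
    cols = []
    for c in covariates:
        if c in _COVARIATE_BUILDERS:
            cols.append(_COVARIATE_BUILDERS[c](data).to_numpy())
        elif c in data.columns:
            cols.append(data[c].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown covariate {c!r}")
    return np.column_stack(cols)


@dataclass
class CoxFit:
    """Fitted proportional-hazards model."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    ties: str = "efron"
    converged: bool = True
    separation: bool = False
    iterations: int = 0

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.exp(self.coef - _Z95 * self.se),
            np.exp(self.coef + _Z95 * self.se),
        )

    @property
    def p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coef / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.ci
        return pd.DataFrame(
            {
                "term": self.names,
                "coef": self.coef,
                "se": self.se,
                "HR": self.hr,
                "ci_low": lo,
                "ci_high": hi,
                "p": self.p,
            }
        )


def _cox_partial_newton(
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Newton-Raphson maximisation of the Cox partial likelihood.

    Events precede censorings at tied times (the censored subject stays
    in the risk set).  Returns (beta, covariance, loglik, iterations,
    converged).
    """
    n, p = X.shape
    order = np.argsort(times, kind="stable")
    t = times[order]
    d = events[order].astype(bool)
    Xs = X[order]
    # tied event groups share a risk set
    ev_times = np.unique(t[d])

    # positions and tie structure are fixed across iterations
    ev_pos = np.searchsorted(t, ev_times, side="left")
    ev_end = np.searchsorted(t, ev_times, side="right")
    tied_groups = []
    single_idx = []   # index of the (single) event subject
    single_pos = []   # risk-set start position
    for i0, i1 in zip(ev_pos, ev_end):
        tied = np.nonzero(d[i0:i1])[0] + i0
        if len(tied) == 1:
            single_idx.append(tied[0])
            single_pos.append(i0)
        else:
            tied_groups.append((i0, tied))
    single_idx = np.asarray(single_idx, dtype=int)
    single_pos = np.asarray(single_pos, dtype=int)

    def ll_grad_hess(beta):
        eta = Xs @ beta
        eta = eta - eta.max()  # numeric stabilisation; cancels in ratios
        w = np.exp(eta)
        # suffix sums over the risk set {i: t_i >= s}
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((Xs * w[:, None])[::-1], axis=0)[::-1]
        xx = Xs[:, :, None] * Xs[:, None, :] * w[:, None, None]
        s2 = np.cumsum(xx[::-1], axis=0)[::-1]
        ll = 0.0
        g = np.zeros(p)
        H = np.zeros((p, p))
        if single_idx.size:
            S0 = s0[single_pos]
            U = s1[single_pos] / S0[:, None]            # (m, p)
            ll += float(eta[single_idx].sum() - np.log(S0).sum())
            g += Xs[single_idx].sum(axis=0) - U.sum(axis=0)
            H -= np.einsum("mij,m->ij", s2[single_pos], 1.0 / S0)
            H += U.T @ U
        for i0, tied in tied_groups:
            dd = len(tied)
            S0, S1, S2 = s0[i0], s1[i0], s2[i0]
            wt = w[tied]
            ll += float(eta[tied].sum())
            if ties == "breslow":
                reps = [(S0, S1, S2)] * dd
            else:
                t0 = wt.sum()
                t1 = (Xs[tied] * wt[:, None]).sum(axis=0)
                t2 = (Xs[tied][:, :, None] * Xs[tied][:, None, :]
                      * wt[:, None, None]).sum(axis=0)
                reps = [
                    (S0 - l / dd * t0, S1 - l / dd * t1, S2 - l / dd * t2)
                    for l in range(dd)
                ]
            for a0, a1, a2 in reps:
                ll -= np.log(a0)
                u = a1 / a0
                g -= u
                H -= a2 / a0 - np.outer(u, u)
            g += Xs[tied].sum(axis=0)
        return ll, g, H

    beta = np.zeros(p)
    ll, g, H = ll_grad_hess(beta)
    it = 0
    converged = False
    n_events = int(d.sum())
    # the gradient is a sum over events, so its floating-point noise
    # floor grows with the event count; stop on either the gradient
    # max-norm or a vanishing Newton step
    g_tol = max(tol, 1e-12 * n_events)
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-H, g, rcond=None)[0]
        # step-halving to guarantee likelihood ascent
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, g_new, H_new = ll_grad_hess(cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, g, H = cand, ll_new, g_new, H_new
        if np.max(np.abs(g)) < g_tol or np.max(np.abs(factor * step)) < 1e-10:
            converged = True
            break
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, ll, it, converged


_CAUSE_LABELS = ("NRM", "relapse", "death")


def fit_cause_specific_cox(
    cohort: Cohort | LandmarkCohort | pd.DataFrame,
    cause: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    ties: str = "efron",
) -> CoxFit:
    """Cause-specific Cox model; competing events are censored.

    cause="NRM": death without prior relapse (relapse censors);
    cause="relapse": relapse/progression (event-free death censors);
    cause="death": all-cause death.
    """
    if cause not in _CAUSE_LABELS:
        raise ValueError(f"cause must be one of {_CAUSE_LABELS}")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    data = cohort if isinstance(cohort, pd.DataFrame) else cohort.data
    rel = data["t_relapse"].to_numpy(dtype=float)
    dth = data["t_death"].to_numpy(dtype=float)
    last = data["t_last_fu"].to_numpy(dtype=float)
    relapsed = ~np.isnan(rel)
    dead = ~np.isnan(dth)
    if cause == "death":
        times = np.where(dead, dth, last)
        events = dead
    elif cause == "relapse":
        times = np.where(relapsed, rel, np.where(dead, dth, last))
        events = relapsed
    else:  # NRM: event-free death; relapse is a competing (censoring) event
        times = np.where(relapsed, rel, np.where(dead, dth, last))
        events = dead & ~relapsed
    if not events.any():
        raise ValueError(f"no events of cause {cause!r}")
    X = build_design(data, covariates)
    beta, cov, ll, it, converged = _cox_partial_newton(
        times, events.astype(int), X, ties=ties
    )
    se = np.sqrt(np.diag(cov))
    separation = bool(np.any(np.abs(beta) > 15) or np.any(~np.isfinite(se)))
    if separation:
        se = np.where(np.isfinite(se), se, np.inf)
    return CoxFit(
        names=list(covariates), coef=beta, se=se, loglik=ll,
        n=len(data), n_events=int(events.sum()), ties=ties,
        converged=converged, separation=separation, iterations=it,
    )


# ---------------------------------------------------------------------------
# additive excess-hazard model (full likelihood, piecewise baseline)
# ---------------------------------------------------------------------------

@dataclass
class ExcessCoxFit:
    """Fitted additive excess-hazard model.

    ``baseline_rates[k]`` is the excess baseline hazard (per year) on
    ``[baseline_breaks[k], baseline_breaks[k+1])`` of the fitting
    window; coefficients are log hazard ratios on the excess hazard.
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    baseline_breaks: np.ndarray
    baseline_rates: np.ndarray
    window: tuple[float, float]
    loglik: float
    n: int
    n_events: int
    iterations: int
    grad_norm: float
    converged: bool = True
    clamping: ClampCounter = field(default_factory=ClampCounter)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.exp(self.coef - _Z95 * self.se),
            np.exp(self.coef + _Z95 * self.se),
        )

    @property
    def p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coef / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.ci
        return pd.DataFrame(
            {
                "term": self.names,
                "coef": self.coef,
                "se": self.se,
                "HR": self.hr,
                "ci_low": lo,
                "ci_high": hi,
                "p": self.p,
                "window": f"{self.window[0]:g}-{self.window[1]:g}y",
            }
        )


def fit_excess_cox(
    cohort: Cohort | LandmarkCohort,
    tables: LifeTableCollection,
    covariates: Sequence[str],
    breaks: Sequence[float],
    window: tuple[float, float],
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ExcessCoxFit:
    """Fit the additive excess-hazard model on a time window.

    ``window = (t_a, t_b)`` and ``breaks`` are on the time-since-HCT
    clock; for a landmark population ``t_a`` must not precede the
    landmark.  The event is death from any cause; subjects event-free
    past ``t_b`` are administratively censored at ``t_b``.  Full
    likelihood in (beta, log baseline), Newton with step-halving.
    """
    from .decompose import _pop_interp_groups

    data = cohort.data
    offset = getattr(cohort, "landmark", 0.0)
    t_a, t_b = float(window[0]), float(window[1])
    if not 0 <= t_a < t_b:
        raise ValueError("window must satisfy 0 <= t_a < t_b")
    if t_a < offset - 1e-9:
        raise ValueError(
            f"window start {t_a} precedes the landmark {offset}"
        )
    breaks = np.asarray(breaks, dtype=float)
    if breaks[0] != t_a or breaks[-1] != t_b or np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must partition the window [t_a, t_b]")

    dth = data["t_death"].to_numpy(dtype=float)
    last = data["t_last_fu"].to_numpy(dtype=float)
    dead = ~np.isnan(dth)
    # absolute (since-HCT) clock
    exit_abs = offset + np.where(dead, dth, last)
    a = t_a
    x_abs = np.minimum(exit_abs, t_b)
    include = x_abs > a + 1e-12
    if not include.any():
        raise ValueError("no person-time inside the window")
    data = data.loc[include].reset_index(drop=True)
    dead = dead[include]
    exit_abs = exit_abs[include]
    x_abs = x_abs[include]
    delta = dead & (exit_abs <= t_b + 1e-12)
    v_abs = np.where(delta, exit_abs, np.nan)

    counter = ClampCounter()
    horizon = t_b + 1.0
    gidx, interps = _pop_interp_groups(data, tables, horizon, counter)

    n = len(data)
    K = len(breaks) - 1
    # exposure in each baseline segment
    E = np.zeros((n, K))
    for k in range(K):
        E[:, k] = np.clip(
            np.minimum(x_abs, breaks[k + 1]) - np.maximum(a, breaks[k]), 0, None
        )
    # population hazard at the death time and segment of the death time
    lam_pop_ev = np.zeros(n)
    k_ev = np.zeros(n, dtype=int)
    pop_const = 0.0
    for i in range(n):
        knots, cum = interps[gidx[i]]
        pop_const += float(np.interp(x_abs[i], knots, cum) - np.interp(a, knots, cum))
        if delta[i]:
            v = v_abs[i]
            j = int(np.clip(np.searchsorted(knots, v, side="right") - 1, 0, len(knots) - 2))
            lam_pop_ev[i] = (cum[j + 1] - cum[j]) / (knots[j + 1] - knots[j])
            k_ev[i] = int(np.clip(np.searchsorted(breaks, v, side="right") - 1, 0, K - 1))
    X = build_design(data, covariates)
    p = X.shape[1]
    ev = np.nonzero(delta)[0]
    if ev.size == 0:
        raise ValueError("no deaths inside the window")

    # starting values: beta = 0, baseline from crude event/exposure rates
    exp_tot = E.sum(axis=0)
    d_seg = np.bincount(k_ev[ev], minlength=K).astype(float)
    gamma = np.log(np.maximum(d_seg, 0.5) / np.maximum(exp_tot, 1e-9))
    beta = np.zeros(p)

    X_ev = X[ev]
    kev = k_ev[ev]
    lam_pop_e = lam_pop_ev[ev]
    seg_onehot = np.zeros((len(ev), K))
    seg_onehot[np.arange(len(ev)), kev] = 1.0

    def ll_grad_hess(beta, gamma):
        lam0 = np.exp(gamma)
        eta = X @ beta
        w = np.exp(eta)
        cumE = E @ lam0                      # Lambda_0,i
        lam_ev = lam0[kev] * w[ev]
        denom = lam_pop_e + lam_ev
        if np.any(denom <= 0):
            return -np.inf, None, None
        ll = float(np.sum(np.log(denom)) - np.sum(w * cumE) - pop_const)
        u = lam_ev / denom                   # in (0, 1]
        uu = u * (1.0 - u)
        g_beta = X_ev.T @ u - X.T @ (w * cumE)
        g_gam = seg_onehot.T @ u - lam0 * (E.T @ w)
        H_bb = (X_ev * uu[:, None]).T @ X_ev - (X * (w * cumE)[:, None]).T @ X
        H_bg = (X_ev * uu[:, None]).T @ seg_onehot - X.T @ (E * (w[:, None]) * lam0[None, :])
        H_gg = np.diag(seg_onehot.T @ uu - lam0 * (E.T @ w))
        g = np.concatenate([g_beta, g_gam])
        H = np.block([[H_bb, H_bg], [H_bg.T, H_gg]])
        return ll, g, H

    theta = np.concatenate([beta, gamma])
    ll, g, H = ll_grad_hess(beta, gamma)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-H, g, rcond=None)[0]
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step = step * (5.0 / norm)
        factor = 1.0
        for _ in range(40):
            cand = theta + factor * step
            cand[p:] = np.maximum(cand[p:], -25.0)
            ll_new, g_new, H_new = ll_grad_hess(cand[:p], cand[p:])
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                break
            factor /= 2.0
        else:
            break
        theta, ll, g, H = cand, ll_new, g_new, H_new
        if (
            np.max(np.abs(g)) < max(tol, 1e-12 * len(ev))
            or np.max(np.abs(factor * step)) < 1e-10
        ):
            converged = True
            break
    if not converged and np.max(np.abs(g)) > 1e-4:
        raise RuntimeError(
            f"excess-hazard fit did not converge after {it} iterations "
            f"(gradient max-norm {np.max(np.abs(g)):.2e})"
        )
    beta, gamma = theta[:p], theta[p:]
    # unbounded-likelihood guard: a baseline segment collapsing to zero
    # while it contains deaths with zero population hazard
    lam0 = np.exp(gamma)
    for k in range(K):
        in_seg = kev == k
        if lam0[k] < 1e-10 and in_seg.any() and np.any(lam_pop_e[in_seg] <= 0):
            raise RuntimeError(
                f"baseline segment {k} collapsed to zero with unmatched "
                "deaths present (unbounded likelihood)"
            )
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.diag(cov)[:p])
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return ExcessCoxFit(
        names=list(covariates),
        coef=beta,
        se=se,
        baseline_breaks=breaks,
        baseline_rates=lam0,
        window=(t_a, t_b),
        loglik=ll,
        n=n,
        n_events=int(delta.sum()),
        iterations=it,
        grad_norm=float(np.max(np.abs(g))),
        converged=converged,
        clamping=counter,
    )
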