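"""Period life tables and matched population hazards.

Relative-survival methods compare the mortality observed in a patient
cohort with the mortality an age/sex/country/calendar-year matched
member of the general population would experience.  This module holds
the population side of that comparison:

* :class:`LifeTable` — a grid of annual death probabilities ``q(age, year)``
  in the layout of Human Mortality Database (HMD) period tables;
* :func:`build_synthetic_lifetable` — Gompertz–Makeham tables with an
  optional secular improvement trend, used when real HMD files are not
  available (they are not redistributable);
* :func:`read_hmd_1x1` — a reader for the HMD period life-table 1x1
  text dialect;
* :func:`pop_cumhazard` — the cumulative population hazard of a matched
  subject over an interval of follow-up time, integrating the
  piecewise-constant hazard along the Lexis diagonal (attained age and
  calendar year advance together with follow-up time);
* :func:`expected_survival_ederer2` — the Ederer II expected-survival
  curve of a cohort (population hazard averaged over the risk set).

Conventions: annual probabilities are converted to hazards by
``h = -ln(1 - q)``, constant within each one-year age x year Lexis cell,
which makes all cumulative hazards exact.  Time is measured in years
(1 year = 365.25 days for any date arithmetic).  Ages above the terminal
age use the terminal row; years outside the grid are clamped to the
nearest boundary year.  Clamping is counted, never silent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "LifeTableCollection",
    "MatchProfile",
    "ExpectedSurvivalCurve",
    "ClampCounter",
    "build_synthetic_lifetable",
    "read_hmd_1x1",
    "lifetable_to_csv",
    "lifetable_from_csv",
    "pop_cumhazard",
    "expected_survival_ederer2",
]

DAYS_PER_YEAR = 365.25

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)


class LifeTableError(ValueError):
    """Invalid life-table content or parameters."""


@dataclass
class ClampCounter:
    """Counts out-of-grid lookups resolved by clamping.

    Surfaced in analysis manifests so that long follow-up of old
    patients running off the table never passes silently.
    """

    age_high: int = 0
    year_low: int = 0
    year_high: int = 0

    @property
    def total(self) -> int:
        return self.age_high + self.year_low + self.year_high

    def merge(self, other: "ClampCounter") -> None:
        self.age_high += other.age_high
        self.year_low += other.year_low
        self.year_high += other.year_high


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities ``q(age, year)`` for one sex and country.

    Parameters
    ----------
    sex:
        ``"male"`` or ``"female"``.
    country:
        Country code (free-form string, e.g. ``"DE"``).
    age_start, year_start:
        First age (completed years) and first calendar year of the grid.
    q:
        2-D array of shape ``(n_ages, n_years)`` with annual death
        probabilities.  All cells must lie in ``[0, 1)`` except the
        terminal-age row, which may equal 1.
    """

    sex: str
    country: str
    age_start: int
    year_start: int
    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if self.sex not in SEXES:
            raise LifeTableError(f"unknown sex {self.sex!r}")
        if q.ndim != 2 or q.size == 0:
            raise LifeTableError("q must be a non-empty 2-D array")
        if np.any(~np.isfinite(q)) or np.any(q < 0) or np.any(q > 1):
            raise LifeTableError("q cells must be finite and within [0, 1]")
        if q.shape[0] > 1 and np.any(q[:-1] >= 1):
            age = int(np.argmax(np.any(q[:-1] >= 1, axis=1))) + self.age_start
            raise LifeTableError(
                f"q >= 1 below the terminal age (first at age {age})"
            )
        # hazard per cell; q == 1 in the terminal row maps to +inf which
        # is handled by the integrator (certain death within the cell)
        with np.errstate(divide="ignore"):
            h = -np.log1p(-q)
        object.__setattr__(self, "_h", h)

    # -- grid accessors -------------------------------------------------
    @property
    def ages(self) -> np.ndarray:
        return self.age_start + np.arange(self.q.shape[0])

    @property
    def age_max(self) -> int:
        return self.age_start + self.q.shape[0] - 1

    @property
    def years(self) -> np.ndarray:
        return self.year_start + np.arange(self.q.shape[1])

    @property
    def year_max(self) -> int:
        return self.year_start + self.q.shape[1] - 1

    @property
    def year_invariant(self) -> bool:
        """True when q does not depend on calendar year (no secular trend)."""
        return bool(np.all(self.q == self.q[:, :1]))

    def hazard(
        self, age: int, year: int, counter: ClampCounter | None = None
    ) -> float:
        """Hazard ``-ln(1-q)`` of the cell containing (age, year), clamped."""
        i = age - self.age_start
        j = year - self.year_start
        if i < 0:
            raise LifeTableError(
                f"age {age} below table start {self.age_start}"
            )
        if i >= self.q.shape[0]:
            i = self.q.shape[0] - 1
            if counter is not None:
                counter.age_high += 1
        if j < 0:
            j = 0
            if counter is not None:
                counter.year_low += 1
        elif j >= self.q.shape[1]:
            j = self.q.shape[1] - 1
            if counter is not None:
                counter.year_high += 1
        return float(self._h[i, j])


@dataclass(frozen=True)
class MatchProfile:
    """Matching covariates of one subject: entry age, sex, country, year.

    ``age_at_entry`` and ``year_at_entry`` may be fractional; the subject
    then crosses Lexis cell boundaries at fractional follow-up times.
    """

    age_at_entry: float
    sex: str
    country: str
    year_at_entry: float

    def __post_init__(self) -> None:
        if self.age_at_entry < 0:
            raise ValueError("age_at_entry must be non-negative")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")


class LifeTableCollection:
    """Lookup of life tables by (country, sex)."""

    def __init__(self, tables: Iterable[LifeTable]):
        self._tables: dict[tuple[str, str], LifeTable] = {}
        for t in tables:
            self._tables[(t.country, t.sex)] = t
        if not self._tables:
            raise LifeTableError("empty life-table collection")
        self._interp_cache: dict = {}

    def __iter__(self):
        return iter(self._tables.values())

    @property
    def countries(self) -> set[str]:
        return {c for c, _ in self._tables}

    def get(self, country: str, sex: str) -> LifeTable:
        try:
            return self._tables[(country, sex)]
        except KeyError:
            raise LifeTableError(
                f"no life table for country={country!r}, sex={sex!r}"
            ) from None

    # cumulative-hazard interpolators are cached because registry cohorts
    # contain many subjects with identical integer entry age; see
    # _cum_hazard_knots
    def cum_hazard_interp(
        self,
        profile: MatchProfile,
        horizon: float,
        counter: ClampCounter | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        table = self.get(profile.country, profile.sex)
        year_inv = table.year_invariant
        key = (
            profile.country,
            profile.sex,
            round(profile.age_at_entry, 9),
            None if year_inv else round(profile.year_at_entry, 9),
            round(horizon, 9),
        )
        hit = self._interp_cache.get(key)
        if hit is not None:
            knots, cum, cached_counter = hit
            if counter is not None:
                counter.merge(cached_counter)
            return knots, cum
        local = ClampCounter()
        knots, cum = _cum_hazard_knots(table, profile, horizon, local)
        self._interp_cache[key] = (knots, cum, local)
        if counter is not None:
            counter.merge(local)
        return knots, cum


# ---------------------------------------------------------------------------
# construction and I/O
# ---------------------------------------------------------------------------

def build_synthetic_lifetable(
    a: float,
    b: float,
    c: float,
    r: float,
    age_range: tuple[int, int],
    year_range: tuple[int, int],
    sex: str,
    country: str,
) -> LifeTable:
    """Gompertz–Makeham period table with a secular improvement trend.

    The hazard at completed age ``x`` in calendar year ``y`` is
    ``(a + b * exp(c * x)) * exp(-r * (y - year_range[0]))``, so the
    annual death probability is ``q = 1 - exp(-hazard)``.  ``a`` is the
    age-independent (Makeham) term, ``b`` and ``c`` the Gompertz level
    and slope, and ``r`` the annual rate of mortality improvement.
    """
    if not (a >= 0 and b > 0 and c > 0 and 0 <= r < 0.1):
        raise LifeTableError(
            "require a >= 0, b > 0, c > 0, 0 <= r < 0.1 "
            f"(got a={a}, b={b}, c={c}, r={r})"
        )
    a0, a1 = age_range
    y0, y1 = year_range
    if not (0 <= a0 <= a1 <= 110):
        raise LifeTableError(f"age_range must be within [0, 110], got {age_range}")
    if y1 < y0:
        raise LifeTableError(f"empty year_range {year_range}")
    ages = np.arange(a0, a1 + 1)
    years = np.arange(y0, y1 + 1)
    haz = (a + b * np.exp(c * ages))[:, None] * np.exp(-r * (years - y0))[None, :]
    q = -np.expm1(-haz)
    below_terminal = q[:-1] if len(ages) > 1 else q[:0]
    if np.any(below_terminal >= 1):
        i, j = np.argwhere(below_terminal >= 1)[0]
        raise LifeTableError(
            "parameters give q >= 1 below the terminal age "
            f"(first at age {ages[i]}, year {years[j]})"
        )
    return LifeTable(sex=sex, country=country, age_start=a0, year_start=y0, q=q)


_HMD_COLUMNS = ["Year", "Age", "mx", "qx", "ax", "lx", "dx", "Lx", "Tx", "ex"]


class HMDParseError(ValueError):
    """Malformed HMD 1x1 life-table text."""


def read_hmd_1x1(stream, sex: str, country: str) -> LifeTable:
    """Parse an HMD period life-table 1x1 text file into a :class:`LifeTable`.

    The dialect: free-text header lines, then a header row naming the
    columns ``Year Age mx qx ax lx dx Lx Tx ex``, then whitespace-
    delimited data rows.  The terminal age token ``110+`` maps to age
    110.  The HMD missing marker ``"."`` in qx is rejected with the
    offending cell named (matched expected survival cannot be computed
    through a hole in the table).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    rows: list[tuple[int, int, float]] = []
    header_seen = False
    for lineno, raw in enumerate(stream, start=1):
        parts = raw.split()
        if not parts:
            continue
        if not header_seen:
            if parts[0] == "Year" and "Age" in parts:
                if "qx" not in parts:
                    raise HMDParseError(
                        f"line {lineno}: header has no qx column"
                    )
                header_seen = True
                qx_idx = parts.index("qx")
                age_idx = parts.index("Age")
            continue
        if len(parts) <= max(qx_idx, age_idx):
            raise HMDParseError(f"line {lineno}: too few columns")
        year_tok, age_tok, qx_tok = parts[0], parts[age_idx], parts[qx_idx]
        try:
            year = int(year_tok)
        except ValueError:
            raise HMDParseError(f"line {lineno}: bad Year token {year_tok!r}")
        age = 110 if age_tok == "110+" else None
        if age is None:
            try:
                age = int(age_tok)
            except ValueError:
                raise HMDParseError(f"line {lineno}: bad Age token {age_tok!r}")
        if qx_tok == ".":
            raise HMDParseError(
                f"line {lineno}: missing qx at age {age}, year {year}"
            )
        try:
            qx = float(qx_tok)
        except ValueError:
            raise HMDParseError(f"line {lineno}: bad qx token {qx_tok!r}")
        if not 0 <= qx <= 1:
            raise HMDParseError(
                f"line {lineno}: qx={qx} outside [0, 1] at age {age}, year {year}"
            )
        rows.append((year, age, qx))
    if not header_seen:
        raise HMDParseError("no HMD column header line found")
    if not rows:
        raise HMDParseError("no data rows after header")
    years = sorted({y for y, _, _ in rows})
    ages = sorted({a for _, a, _ in rows})
    if years != list(range(years[0], years[-1] + 1)):
        raise HMDParseError(f"non-contiguous year grid {years}")
    if ages != list(range(ages[0], ages[-1] + 1)):
        raise HMDParseError(f"non-contiguous age grid {ages}")
    q = np.full((len(ages), len(years)), np.nan)
    for year, age, qx in rows:
        q[age - ages[0], year - years[0]] = qx
    if np.any(np.isnan(q)):
        i, j = np.argwhere(np.isnan(q))[0]
        raise HMDParseError(
            f"cell age {ages[0] + i}, year {years[0] + j} absent from the grid"
        )
    return LifeTable(
        sex=sex, country=country, age_start=ages[0], year_start=years[0], q=q
    )


def lifetable_to_csv(table: LifeTable) -> pd.DataFrame:
    """Tidy serialization: columns country, sex, year, age, qx."""
    ages, years = np.meshgrid(table.ages, table.years, indexing="ij")
    return pd.DataFrame(
        {
            "country": table.country,
            "sex": table.sex,
            "year": years.ravel(),
            "age": ages.ravel(),
            "qx": table.q.ravel(),
        }
    )


def lifetable_from_csv(df: pd.DataFrame) -> LifeTable:
    """Inverse of :func:`lifetable_to_csv` (one country/sex per frame)."""
    countries = df["country"].unique()
    sexes = df["sex"].unique()
    if len(countries) != 1 or len(sexes) != 1:
        raise LifeTableError(
            "lifetable_from_csv expects a single country and sex per frame"
        )
    pivot = df.pivot(index="age", columns="year", values="qx").sort_index()
    pivot = pivot[sorted(pivot.columns)]
    ages = pivot.index.to_numpy()
    years = np.asarray(sorted(pivot.columns))
    if np.any(np.diff(ages) != 1) or np.any(np.diff(years) != 1):
        raise LifeTableError("non-contiguous age or year grid in CSV")
    if pivot.isna().any().any():
        raise LifeTableError("missing qx cells in CSV")
    return LifeTable(
        sex=str(sexes[0]),
        country=str(countries[0]),
        age_start=int(ages[0]),
        year_start=int(years[0]),
        q=pivot.to_numpy(),
    )


# ---------------------------------------------------------------------------
# cumulative population hazard along the Lexis diagonal
# ---------------------------------------------------------------------------

def _cum_hazard_knots(
    table: LifeTable,
    profile: MatchProfile,
    horizon: float,
    counter: ClampCounter | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Knots and cumulative hazard values of the matched step hazard.

    The hazard is constant between consecutive knots, so the cumulative
    hazard is piecewise linear and ``np.interp`` on the returned arrays
    is exact for any 0 <= t <= horizon.
    """
    a0 = profile.age_at_entry
    y0 = profile.year_at_entry
    # follow-up times at which the attained age or calendar year crosses
    # an integer boundary
    age_cross = np.arange(np.ceil(a0 + 1e-12) - a0, horizon, 1.0)
    if table.year_invariant:
        year_cross = np.empty(0)
    else:
        year_cross = np.arange(np.ceil(y0 + 1e-12) - y0, horizon, 1.0)
    knots = np.unique(np.concatenate([[0.0], age_cross, year_cross, [horizon]]))
    knots = knots[(knots >= 0) & (knots <= horizon + 1e-12)]
    mids = 0.5 * (knots[:-1] + knots[1:])
    haz = np.array(
        [
            table.hazard(int(np.floor(a0 + u)), int(np.floor(y0 + u)), counter)
            for u in mids
        ]
    )
    cum = np.concatenate([[0.0], np.cumsum(haz * np.diff(knots))])
    return knots, cum


def pop_cumhazard(
    table: LifeTable,
    profile: MatchProfile,
    t0: float,
    t1: float,
    counter: ClampCounter | None = None,
) -> float:
    """Cumulative matched population hazard over follow-up ``[t0, t1]``.

    Integrates ``h(u) = -ln(1 - q(floor(age0+u), floor(year0+u)))``
    exactly, including fractional crossings of Lexis cell boundaries.
    """
    if not 0 <= t0 <= t1:
        raise ValueError(f"require 0 <= t0 <= t1, got ({t0}, {t1})")
    if t0 == t1:
        return 0.0
    knots, cum = _cum_hazard_knots(table, profile, t1, counter)
    return float(np.interp(t1, knots, cum) - np.interp(t0, knots, cum))


# ---------------------------------------------------------------------------
# Ederer II expected survival
# ---------------------------------------------------------------------------

@dataclass
class ExpectedSurvivalCurve:
    """Matched expected survival of a cohort.

    ``S(t) = exp(-integral of the risk-set mean population hazard)``;
    the Ederer II estimator.  ``flat_from`` is set when the risk set
    empties before the end of the grid, after which the curve is carried
    forward flat.
    """

    time: np.ndarray
    survival: np.ndarray
    estimator: str = "Ederer II"
    flat_from: float | None = None
    clamping: ClampCounter = field(default_factory=ClampCounter)

    def at(self, t: float) -> float:
        i = int(np.searchsorted(self.time, t, side="right")) - 1
        if i < 0:
            return 1.0
        return float(self.survival[i])


def expected_survival_ederer2(
    profiles: Sequence[MatchProfile],
    followup: Sequence[float],
    tables: LifeTableCollection | LifeTable,
    grid: Sequence[float],
) -> ExpectedSurvivalCurve:
    """Ederer II expected survival of a cohort on ``grid``.

    At each time the population hazard is averaged over the subjects
    still under observation (follow-up time not yet reached), so the
    expected curve shares the observed cohort's censoring pattern.  The
    integration runs on the union of ``grid``, the subjects' exit times
    and their hazard-change knots, and is therefore exact for step
    hazards; when the risk set empties the curve is extended flat and
    flagged via ``flat_from``.
    """
    if isinstance(tables, LifeTable):
        tables = LifeTableCollection([tables])
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be sorted, start at 0, and be strictly increasing")
    followup = np.asarray(followup, dtype=float)
    if len(profiles) == 0 or len(profiles) != len(followup):
        raise ValueError("need one follow-up time per profile (and at least one)")
    horizon = float(grid[-1])
    counter = ClampCounter()
    interp_ids: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    subj_group = np.empty(len(profiles), dtype=int)
    group_key: dict[tuple, int] = {}
    group_interp: list[tuple[np.ndarray, np.ndarray]] = []
    for i, p in enumerate(profiles):
        key = (p.country, p.sex, round(p.age_at_entry, 9), round(p.year_at_entry, 9))
        g = group_key.get(key)
        if g is None:
            g = len(group_interp)
            group_key[key] = g
            group_interp.append(
                tables.cum_hazard_interp(p, horizon + 1.0, counter)
            )
        subj_group[i] = g
    n_groups = len(group_interp)

    knots = np.unique(
        np.concatenate(
            [grid, np.clip(followup, 0, horizon)]
            + [k[(k > 0) & (k < horizon)] for k, _ in group_interp]
        )
    )
    knots = knots[(knots >= 0) & (knots <= horizon)]
    b = knots[1:]
    # accumulate risk-set size and risk-set hazard mass per interval,
    # streamed per matching group (subjects sharing age/sex/country/year
    # share one hazard trajectory)
    n_risk = np.zeros(len(b))
    sum_dH = np.zeros(len(b))
    for g in range(n_groups):
        fu = np.sort(followup[subj_group == g])
        # number with follow-up >= b (tolerate fp noise at knot ties)
        at_risk = len(fu) - np.searchsorted(fu, b - 1e-12, side="left")
        k, c = group_interp[g]
        dH = np.diff(np.interp(knots, k, c))
        n_risk += at_risk
        sum_dH += at_risk * dH
    mean_dH = np.zeros(len(b))
    ok = n_risk > 0
    mean_dH[ok] = sum_dH[ok] / n_risk[ok]
    flat_from = None
    if not ok.all():
        first_empty = int(np.argmax(~ok))
        flat_from = float(knots[first_empty])
        mean_dH[~ok] = 0.0
    cum = np.concatenate([[0.0], np.cumsum(mean_dH)])
    surv = np.exp(-np.interp(grid, knots, cum))
    return ExpectedSurvivalCurve(
        time=grid, survival=surv, flat_from=flat_from, clamping=counter
    )
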