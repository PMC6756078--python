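"""Life tables, matched cumulative hazards and expected survival."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from latemort.lifetables import (
    ClampCounter,
    HMDParseError,
    LifeTable,
    LifeTableCollection,
    LifeTableError,
    MatchProfile,
    build_synthetic_lifetable,
    expected_survival_ederer2,
    lifetable_from_csv,
    lifetable_to_csv,
    pop_cumhazard,
    read_hmd_1x1,
)

from conftest import constant_table


class TestSyntheticTable:
    def test_gompertz_makeham_closed_form(self):
        t = build_synthetic_lifetable(
            a=0.0, b=1e-5, c=0.1, r=0.0, age_range=(0, 110),
            year_range=(2000, 2005), sex="male", country="XX",
        )
        expected = 1.0 - np.exp(-1e-5 * np.exp(0.1 * 60))
        assert t.q[60, 0] == pytest.approx(expected, rel=1e-12)

    def test_vanishing_gompertz_gives_zero_hazard(self):
        t = build_synthetic_lifetable(
            a=0.0, b=1e-300, c=0.1, r=0.0, age_range=(0, 80),
            year_range=(2000, 2001), sex="male", country="XX",
        )
        assert np.allclose(t.q, 0.0, atol=1e-250)

    def test_no_secular_trend_is_year_invariant(self):
        t = build_synthetic_lifetable(
            a=1e-4, b=3e-5, c=0.09, r=0.0, age_range=(0, 110),
            year_range=(2000, 2010), sex="female", country="XX",
        )
        assert t.year_invariant
        assert np.all(t.q[:, 0:1] == t.q)

    def test_secular_trend_lowers_later_years(self):
        t = build_synthetic_lifetable(
            a=1e-4, b=3e-5, c=0.09, r=0.01, age_range=(0, 110),
            year_range=(2000, 2010), sex="male", country="XX",
        )
        assert np.all(t.q[:, -1] < t.q[:, 0])

    def test_explosive_parameters_rejected_with_cell(self):
        with pytest.raises(LifeTableError, match="age"):
            build_synthetic_lifetable(
                a=0.0, b=0.5, c=0.2, r=0.0, age_range=(0, 110),
                year_range=(2000, 2001), sex="male", country="XX",
            )

    def test_invalid_parameter_signs_rejected(self):
        with pytest.raises(LifeTableError):
            build_synthetic_lifetable(
                a=-1.0, b=1e-5, c=0.1, r=0.0, age_range=(0, 110),
                year_range=(2000, 2001), sex="male", country="XX",
            )


HMD_FIXTURE = """Sweden, Life tables (period 1x1), Males
Last modified: 2017

  Year  Age  mx  qx  ax  lx  dx  Lx  Tx  ex
  2000  50  0.7  0.5  0.5  100000  50000  75000  100  1.0
  2000  51  0.7  0.6  0.5  50000  30000  35000  25  0.5
"""


class TestHMDReader:
    def test_reads_qx_field(self):
        t = read_hmd_1x1(HMD_FIXTURE, sex="male", country="SE")
        assert t.q[0, 0] == 0.5
        assert t.q[1, 0] == 0.6
        assert list(t.ages) == [50, 51]

    def test_terminal_age_token(self):
        text = (
            "header\nYear Age mx qx ax lx dx Lx Tx ex\n"
            "2000 109 0.5 0.4 0.5 10 4 8 9 1\n"
            "2000 110+ 1.0 1.0 0.5 6 6 3 3 0.5\n"
        )
        t = read_hmd_1x1(text, sex="female", country="SE")
        assert t.age_max == 110
        assert t.q[-1, 0] == 1.0

    def test_missing_marker_names_cell(self):
        text = (
            "Year Age mx qx ax lx dx Lx Tx ex\n"
            "2000 50 0.7 . 0.5 1 1 1 1 1\n"
        )
        with pytest.raises(HMDParseError, match="age 50, year 2000"):
            read_hmd_1x1(text, sex="male", country="SE")

    def test_non_contiguous_grid_rejected(self):
        text = (
            "Year Age mx qx ax lx dx Lx Tx ex\n"
            "2000 50 0.7 0.5 0.5 1 1 1 1 1\n"
            "2000 52 0.7 0.5 0.5 1 1 1 1 1\n"
        )
        with pytest.raises(HMDParseError, match="non-contiguous"):
            read_hmd_1x1(text, sex="male", country="SE")

    def test_qx_out_of_range_reports_line(self):
        text = (
            "Year Age mx qx ax lx dx Lx Tx ex\n"
            "2000 50 0.7 1.5 0.5 1 1 1 1 1\n"
        )
        with pytest.raises(HMDParseError, match="line 2"):
            read_hmd_1x1(text, sex="male", country="SE")

    def test_missing_header_rejected(self):
        with pytest.raises(HMDParseError, match="header"):
            read_hmd_1x1("just some text\n", sex="male", country="SE")


class TestCSVRoundTrip:
    def test_round_trip(self):
        t = build_synthetic_lifetable(
            a=1e-4, b=3e-5, c=0.09, r=0.005, age_range=(0, 110),
            year_range=(2000, 2005), sex="male", country="DE",
        )
        back = lifetable_from_csv(lifetable_to_csv(t))
        assert back.sex == t.sex and back.country == t.country
        np.testing.assert_allclose(back.q, t.q)


class TestPopCumhazard:
    def test_constant_hazard_closed_form(self):
        table = constant_table(0.02)
        p = MatchProfile(50.0, "male", "XX", 2002.0)
        assert pop_cumhazard(table, p, 0, 5) == pytest.approx(
            -5 * np.log(0.98), rel=1e-12
        )

    def test_empty_interval_is_zero(self):
        table = constant_table(0.02)
        p = MatchProfile(50.0, "male", "XX", 2002.0)
        assert pop_cumhazard(table, p, 3.2, 3.2) == 0.0

    def test_fractional_age_cell_split(self):
        """One-year interval starting at age 64.5 spends half a year in
        each of two age cells."""
        q = np.tile(np.linspace(0.01, 0.5, 111)[:, None], (1, 45))
        table = LifeTable("male", "XX", 0, 1995, q)
        p = MatchProfile(64.5, "male", "XX", 2002.0)
        h1 = -np.log1p(-q[64, 0])
        h2 = -np.log1p(-q[65, 0])
        assert pop_cumhazard(table, p, 0, 1) == pytest.approx(
            0.5 * h1 + 0.5 * h2, rel=1e-12
        )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        age=st.floats(18, 80),
        year=st.floats(1996, 2030),
        t0=st.floats(0, 8),
        dt=st.floats(0.01, 8),
    )
    def test_agrees_with_midpoint_quadrature(self, age, year, t0, dt):
        """Exact Lexis integration matches brute-force midpoint quadrature
        of the step hazard.  The quadrature oracle itself mislocates each
        cell boundary by up to half a panel, so the tolerance reflects the
        oracle's resolution (exactness of the integrator is pinned by the
        closed-form and additivity tests)."""
        rng = np.random.default_rng(12345)
        q = np.tile(rng.uniform(0.001, 0.2, 111)[:, None], (1, 45))
        table = LifeTable("male", "XX", 0, 1995, q)
        p = MatchProfile(age, "male", "XX", year)
        t1 = t0 + dt
        val = pop_cumhazard(table, p, t0, t1)
        n_panel = 10_000
        u = t0 + (np.arange(n_panel) + 0.5) / n_panel * dt
        h = np.array(
            [table.hazard(int(np.floor(age + x)), int(np.floor(year + x))) for x in u]
        )
        quad = h.mean() * dt
        # <= 2 boundary crossings per year of follow-up, each mislocated
        # by at most half a panel with a jump bounded by the max hazard
        slack = (2 * dt + 2) * (dt / n_panel) * np.max(-np.log1p(-q))
        assert abs(val - quad) <= slack + 1e-12

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        t1=st.floats(0.01, 20),
        frac=st.floats(0.0, 1.0),
        age=st.floats(20, 70),
    )
    def test_additivity(self, t1, frac, age):
        q = np.tile(np.linspace(0.002, 0.3, 111)[:, None], (1, 45))
        table = LifeTable("female", "XX", 0, 1995, q)
        p = MatchProfile(age, "female", "XX", 2001.3)
        tm = frac * t1
        whole = pop_cumhazard(table, p, 0, t1)
        split = pop_cumhazard(table, p, 0, tm) + pop_cumhazard(table, p, tm, t1)
        assert whole == pytest.approx(split, abs=1e-12, rel=1e-12)

    def test_raising_q_cell_is_monotone(self):
        q = np.full((111, 45), 0.01)
        base = LifeTable("male", "XX", 0, 1995, q)
        q2 = q.copy()
        q2[52, :] = 0.05
        raised = LifeTable("male", "XX", 0, 1995, q2)
        p = MatchProfile(50.0, "male", "XX", 2000.0)
        assert pop_cumhazard(raised, p, 0, 5) > pop_cumhazard(base, p, 0, 5)

    def test_out_of_grid_clamps_and_counts(self):
        table = constant_table(0.02)
        p = MatchProfile(105.0, "male", "XX", 2038.0)
        counter = ClampCounter()
        val = pop_cumhazard(table, p, 0, 10, counter)
        # hazard of the terminal row applies beyond age 110
        assert val == pytest.approx(-10 * np.log(0.98), rel=1e-9)
        assert counter.age_high > 0 and counter.year_high > 0


class TestEdererII:
    def test_single_subject_closed_form(self):
        coll = LifeTableCollection([constant_table(0.02)])
        p = MatchProfile(50.0, "male", "XX", 2002.0)
        curve = expected_survival_ederer2([p], [10.0], coll, np.linspace(0, 5, 51))
        assert curve.at(5) == pytest.approx(0.98**5, rel=1e-12)

    def test_single_subject_equals_pop_cumhazard(self):
        table = constant_table(0.07)
        coll = LifeTableCollection([table])
        p = MatchProfile(63.4, "male", "XX", 2004.2)
        grid = np.array([0.0, 0.7, 1.9, 4.4])
        curve = expected_survival_ederer2([p], [20.0], coll, grid)
        for t in grid[1:]:
            assert curve.at(t) == pytest.approx(
                np.exp(-pop_cumhazard(table, p, 0, t)), rel=1e-12
            )

    def test_zero_hazard_gives_unity(self):
        coll = LifeTableCollection([constant_table(0.0)])
        p = MatchProfile(40.0, "male", "XX", 2005.0)
        curve = expected_survival_ederer2([p, p], [3.0, 7.0], coll, np.linspace(0, 6, 13))
        assert np.all(curve.survival == 1.0)

    def test_two_subject_mean_hazard(self):
        coll = LifeTableCollection(
            [constant_table(0.02, country="AA"), constant_table(0.05, country="BB")]
        )
        pa = MatchProfile(40, "male", "AA", 2001.0)
        pb = MatchProfile(40, "male", "BB", 2001.0)
        curve = expected_survival_ederer2([pa, pb], [9, 9], coll, np.array([0.0, 1, 2, 3]))
        ha, hb = -np.log(0.98), -np.log(0.95)
        assert curve.at(3) == pytest.approx(np.exp(-3 * (ha + hb) / 2), rel=1e-12)

    def test_risk_set_conditioning_after_exit(self):
        """After the shorter follow-up ends, only the remaining subject's
        hazard drives the curve."""
        coll = LifeTableCollection(
            [constant_table(0.02, country="AA"), constant_table(0.05, country="BB")]
        )
        pa = MatchProfile(40, "male", "AA", 2001.0)
        pb = MatchProfile(40, "male", "BB", 2001.0)
        curve = expected_survival_ederer2([pa, pb], [10, 2], coll, np.array([0.0, 2, 4]))
        ha, hb = -np.log(0.98), -np.log(0.95)
        expected = np.exp(-(2 * (ha + hb) / 2 + 2 * ha))
        assert curve.at(4) == pytest.approx(expected, rel=1e-12)

    def test_empty_risk_set_extends_flat(self):
        coll = LifeTableCollection([constant_table(0.1)])
        p = MatchProfile(50.0, "male", "XX", 2002.0)
        curve = expected_survival_ederer2([p], [2.0], coll, np.array([0.0, 1, 2, 3, 4]))
        assert curve.flat_from == pytest.approx(2.0)
        assert curve.at(4) == pytest.approx(curve.at(2), rel=1e-12)

    def test_raising_q_never_increases_expected_survival(self):
        coll_lo = LifeTableCollection([constant_table(0.02)])
        coll_hi = LifeTableCollection([constant_table(0.03)])
        p = MatchProfile(55.0, "male", "XX", 2003.0)
        grid = np.linspace(0, 8, 17)
        s_lo = expected_survival_ederer2([p], [10.0], coll_lo, grid).survival
        s_hi = expected_survival_ederer2([p], [10.0], coll_hi, grid).survival
        assert np.all(s_hi <= s_lo + 1e-15)

    def test_bad_grid_rejected(self):
        coll = LifeTableCollection([constant_table(0.02)])
        p = MatchProfile(50.0, "male", "XX", 2002.0)
        with pytest.raises(ValueError):
            expected_survival_ederer2([p], [5.0], coll, np.array([1.0, 2.0]))


class TestLifeTableValidation:
    def test_q_above_one_below_terminal_rejected(self):
        q = np.full((111, 3), 0.01)
        q[50, :] = 1.0
        with pytest.raises(LifeTableError, match="age 50"):
            LifeTable("male", "XX", 0, 2000, q)

    def test_terminal_q_of_one_accepted(self):
        q = np.full((111, 3), 0.01)
        q[110, :] = 1.0
        t = LifeTable("male", "XX", 0, 2000, q)
        assert t.q[110, 0] == 1.0

    def test_missing_table_lookup(self):
        coll = LifeTableCollection([constant_table(0.02)])
        with pytest.raises(LifeTableError, match="country"):
            coll.get("YY", "male")
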