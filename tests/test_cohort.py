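"""Simulator, analytic oracle and scenario calibration."""

import numpy as np
import pandas as pd
import pytest

from latemort.cohort import (
    CalibrationTarget,
    ScenarioError,
    calibrate_scenario,
    landmark_implied_curves,
    model_implied_curves,
    postrelapse_survival_implied,
    s1_base_scenario,
    sample_cohort,
)
from latemort.lifetables import LifeTableCollection, MatchProfile, pop_cumhazard
from latemort.survival import (
    aalen_johansen,
    competing_risk_codes,
    efs_times,
    kaplan_meier,
    os_times,
)

from conftest import constant_table, flat_tables, simple_scenario


class TestSampler:
    def test_no_event_limit_censors_at_closure(self):
        """All hazards zero, entry fixed 4 years before closure: every
        subject is censored alive at exactly 4 years."""
        sc = simple_scenario()
        coh = sample_cohort(sc, flat_tables(0.0), 200, seed=5)
        d = coh.data
        assert d["t_death"].isna().all() and d["t_relapse"].isna().all()
        np.testing.assert_allclose(d["t_last_fu"], 4.0, atol=1e-12)
        assert (d["death_cause_sim"] == "none").all()

    def test_fixed_seed_reproducibility(self, s1, tables_s1):
        a = sample_cohort(s1, tables_s1, 100, seed=42)
        b = sample_cohort(s1, tables_s1, 100, seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_substreams_stable_under_larger_n(self, s1, tables_s1):
        small = sample_cohort(s1, tables_s1, 50, seed=42)
        large = sample_cohort(s1, tables_s1, 80, seed=42)
        pd.testing.assert_frame_equal(small.data, large.data.iloc[:50])

    def test_pure_population_cohort_matches_expected_survival(self):
        """With relapse and excess hazards zero, all deaths are population
        deaths and the 5-year death fraction matches the matched
        life-table survival."""
        sc = simple_scenario(age=70, entry=(2008.0, 2008.0), closure=2017.0)
        tables = flat_tables(0.03)
        n = 20_000
        coh = sample_cohort(sc, tables, n, seed=9)
        d = coh.data
        causes = set(d.loc[d["t_death"].notna(), "death_cause_sim"])
        assert causes <= {"population"}
        p_dead5 = float((d["t_death"] <= 5).sum()) / n
        table = tables.get("XX", "male")
        prof = MatchProfile(70, "male", "XX", 2008.0)
        expected = 1 - np.exp(-pop_cumhazard(table, prof, 0, 5))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(p_dead5 - expected) < 3 * se

    def test_missing_country_table_rejected(self, s1):
        only_xx = LifeTableCollection(
            [constant_table(0.01, sex=s) for s in ("male", "female")]
        )
        with pytest.raises(ScenarioError, match="life tables"):
            sample_cohort(s1, only_xx, 10, seed=1)

    def test_relapse_before_death_invariant(self, cohort_100k):
        d = cohort_100k.data
        both = d["t_relapse"].notna() & d["t_death"].notna()
        assert (d.loc[both, "t_death"] > d.loc[both, "t_relapse"]).all()
        dead = d["t_death"].notna()
        assert (d.loc[dead, "t_last_fu"] == d.loc[dead, "t_death"]).all()

    def test_age_range_matches_scenario(self, cohort_100k):
        ages = cohort_100k.data["age"]
        assert ages.min() >= 18 and ages.max() <= 76


class TestOracleClosedForms:
    def test_all_hazards_zero(self):
        sc = simple_scenario()
        cur = model_implied_curves(sc, flat_tables(0.0), np.linspace(0, 8, 9))
        assert np.allclose(cur.EFS, 1.0) and np.allclose(cur.OS, 1.0)
        assert np.allclose(cur.CIR, 0.0) and np.allclose(cur.NRM, 0.0)

    def test_constant_hazard_competing_risks(self):
        """Single stratum, constant hazards: EFS is exponential in the
        total hazard and each incidence gets its proportional share."""
        lam_rel, lam_exc, q = 0.08, 0.05, 0.02
        sc = simple_scenario(rel=lam_rel, exc=lam_exc)
        tables = flat_tables(q)
        lam_pop = -np.log(1 - q)
        tot = lam_rel + lam_exc + lam_pop
        grid = np.array([0.0, 1.0, 2.0, 4.0])
        cur = model_implied_curves(sc, tables, grid)
        np.testing.assert_allclose(cur.EFS, np.exp(-tot * grid), rtol=1e-9)
        np.testing.assert_allclose(
            cur.NRM_pop, lam_pop / tot * (1 - np.exp(-tot * grid)), rtol=1e-9
        )
        np.testing.assert_allclose(
            cur.NRM_excess, lam_exc / tot * (1 - np.exp(-tot * grid)), rtol=1e-9
        )
        np.testing.assert_allclose(
            cur.CIR, lam_rel / tot * (1 - np.exp(-tot * grid)), rtol=1e-9
        )

    def test_death_after_relapse_closed_form(self):
        """Constant hazards with exponential post-relapse death: the
        double integral has a closed form."""
        lam_rel, lam_d = 0.1, 0.9
        sc = simple_scenario(rel=lam_rel, post=lam_d)
        tables = flat_tables(0.0)
        t = 3.0
        cur = model_implied_curves(sc, tables, np.array([0.0, t]))
        # P(relapse by s, death by t) = int_0^t lam_rel e^{-lam_rel s}
        #   (1 - e^{-lam_d (t-s)}) ds
        analytic = (
            (1 - np.exp(-lam_rel * t))
            - lam_rel / (lam_d - lam_rel)
            * (np.exp(-lam_rel * t) - np.exp(-lam_d * t))
        )
        assert cur.death_after_relapse[-1] == pytest.approx(analytic, rel=1e-6)

    def test_step_halving_convergence(self):
        sc = simple_scenario(rel=0.08, exc=0.05, post=0.7)
        tables = flat_tables(0.02)
        grid = np.array([0.0, 1.0, 3.0, 6.0])
        a = model_implied_curves(sc, tables, grid, step=0.01)
        b = model_implied_curves(sc, tables, grid, step=0.005)
        for name in ("EFS", "CIR", "NRM_pop", "NRM_excess", "death_after_relapse", "OS"):
            assert np.max(np.abs(getattr(a, name) - getattr(b, name))) < 1e-6

    def test_large_step_refused(self):
        sc = simple_scenario(rel=0.08)
        with pytest.raises(ScenarioError, match="step"):
            model_implied_curves(sc, flat_tables(0.0), np.array([0.0, 2.0]), step=0.6)

    def test_stack_identities(self, s1, tables_s1):
        grid = np.linspace(0, 10, 21)
        cur = model_implied_curves(s1, tables_s1, grid)
        np.testing.assert_allclose(cur.EFS + cur.CIR + cur.NRM, 1.0, atol=1e-9)
        np.testing.assert_allclose(cur.NRM_pop + cur.NRM_excess, cur.NRM, atol=1e-12)
        assert np.all(cur.OS >= cur.EFS - 1e-12)
        assert np.all(np.diff(cur.EFS) <= 1e-12)
        assert np.all(np.diff(cur.CIR) >= -1e-10)
        assert np.all(np.diff(cur.NRM_pop) >= -1e-10)


class TestSimulatorOracleAgreement:
    """The stochastic simulator and the deterministic forward equations
    describe the same generating law."""

    def test_marginal_curves_within_monte_carlo_error(self, s1, tables_s1, cohort_100k):
        grid = np.array([0.5, 1, 2, 3, 4, 5, 6, 7, 8, 10.0])
        cur = model_implied_curves(s1, tables_s1, np.concatenate([[0.0], grid]))
        d = cohort_100k.data
        t, e = efs_times(d)
        km_efs = kaplan_meier(t, e)
        t, c = competing_risk_codes(d)
        aj = aalen_johansen(t, c)
        t, e = os_times(d)
        km_os = kaplan_meier(t, e)
        for q in grid:
            i = int(np.searchsorted(cur.time, q))
            for est, curve_val, var in (
                (km_efs.at(q), cur.EFS[i], km_efs.variance),
                (aj.at(1, q), cur.CIR[i], aj.variance[1]),
                (aj.at(2, q), cur.NRM[i], aj.variance[2]),
                (km_os.at(q), cur.OS[i], km_os.variance),
            ):
                # estimator's own (Greenwood/Aalen) standard error
                se = np.sqrt(max(float(var[min(np.searchsorted(
                    km_efs.time if var is km_efs.variance else aj.time
                    if var is not km_os.variance else km_os.time, q), len(var) - 1)]),
                    1e-10))
                assert abs(est - curve_val) < 3.5 * se + 2e-3

    def test_truth_split_matches_oracle_nrm_components(self, s1, tables_s1, cohort_100k):
        """Among simulated event-free deaths by 5y, the fraction labelled
        population matches the oracle's NRM_pop / NRM."""
        cur = model_implied_curves(s1, tables_s1, np.array([0.0, 5.0]))
        d = cohort_100k.data
        ef_death5 = d["t_death"].notna() & d["t_relapse"].isna() & (d["t_death"] <= 5)
        frac_pop = (d.loc[ef_death5, "death_cause_sim"] == "population").mean()
        oracle = cur.NRM_pop[-1] / cur.NRM[-1]
        n = int(ef_death5.sum())
        se = np.sqrt(oracle * (1 - oracle) / n)
        assert abs(frac_pop - oracle) < 3 * se + 1e-3

    def test_censoring_independence(self, tables_s1):
        """Raising loss to follow-up from 0 to 0.05/y moves the large-n
        estimates by well under a percentage point."""
        base = s1_base_scenario()
        import copy

        lossy = copy.deepcopy(base)
        lossy.ltfu_rate = 0.05
        base.ltfu_rate = 0.0
        res = {}
        for name, sc in (("none", base), ("lossy", lossy)):
            coh = sample_cohort(sc, tables_s1, 30_000, seed=77)
            t, e = os_times(coh.data)
            km = kaplan_meier(t, e)
            t, c = competing_risk_codes(coh.data)
            aj = aalen_johansen(t, c)
            res[name] = (km.at(5), aj.at(1, 5), aj.at(2, 5))
        for a, b in zip(res["none"], res["lossy"]):
            assert abs(a - b) < 0.01

    def test_frailty_mixture_agrees_with_oracle(self, tables_s1):
        """With the two-point post-relapse frailty enabled the simulator
        still matches the analytic mixture integration."""
        sc = simple_scenario(rel=0.15, exc=0.03, post=0.5,
                             frail_prob=0.4, frail_loghr=np.log(6.0))
        tables = flat_tables(0.01)
        coh = sample_cohort(sc, tables, 30_000, seed=31)
        cur = model_implied_curves(sc, tables, np.array([0.0, 2.0, 4.0]))
        d = coh.data
        dead_by = lambda q: float(
            (d["t_death"].notna() & (d["t_death"] <= q)
             & d["t_relapse"].notna()).sum()
        ) / len(d)
        for i, q in enumerate((2.0, 4.0)):
            est = dead_by(q)
            oracle = cur.death_after_relapse[i + 1]
            se = np.sqrt(oracle * (1 - oracle) / len(d))
            assert abs(est - oracle) < 3.5 * se + 1e-3


class TestLandmarkOracle:
    def test_landmark_band_weights_reproduce_selection(self, s1, tables_s1, cohort_100k):
        """Oracle landmark curves (EF-selection reweighted) match the
        estimated landmark incidence for the oldest band."""
        from latemort.survival import LandmarkCohort, make_landmark

        lm = make_landmark(cohort_100k, 2.0, "EF")
        sub = lm.data[lm.data["age"] >= 65].reset_index(drop=True)
        t, c = competing_risk_codes(sub)
        aj = aalen_johansen(t, c)
        cur = landmark_implied_curves(s1, tables_s1, 2.0, np.array([0.0, 5.0]), band=3)
        n = len(sub)
        for est, oracle in ((aj.at(1, 5), cur.CIR[-1]), (aj.at(2, 5), cur.NRM[-1])):
            se = np.sqrt(oracle * (1 - oracle) / n)
            assert abs(est - oracle) < 3.5 * se


class TestCalibration:
    def test_fixed_point(self, tables_s1):
        """Targets equal to the base scenario's own implied values leave
        the parameters unchanged."""
        base = s1_base_scenario()
        grid = np.array([0.0, 2.0])
        cur = model_implied_curves(base, tables_s1, grid, step=0.01)
        targets = [CalibrationTarget("efs", float(cur.EFS[-1]), time=2.0)]
        solved, report = calibrate_scenario(
            targets, base, tables_s1, ["rel_seg0"], step=0.01
        )
        assert solved.relapse.rates[0] == pytest.approx(base.relapse.rates[0], rel=1e-6)
        assert report.max_abs_residual < 1e-8

    def test_single_target_efs(self, tables_s1):
        base = s1_base_scenario()
        targets = [CalibrationTarget("efs", 0.47, time=2.0)]
        solved, report = calibrate_scenario(
            targets, base, tables_s1, ["rel_early_scale"], step=0.01
        )
        cur = model_implied_curves(solved, tables_s1, np.array([0.0, 2.0]), step=0.01)
        assert cur.EFS[-1] == pytest.approx(0.47, abs=2e-3)

    def test_exponential_postrelapse_median_closed_form(self):
        """Constant post-relapse hazard, zero population hazard: the
        calibrated rate is exactly ln 2 / median."""
        sc = simple_scenario(rel=0.1, post=1.0)
        tables = flat_tables(0.0)
        target_median = 0.383
        solved, _ = calibrate_scenario(
            [CalibrationTarget("postrel_median", target_median)],
            sc, tables, ["pr_scale_early"], step=0.01,
        )
        # pr_scale_early drives segments [0, 0.5); with all segments equal
        # at the start, the solve leaves a constant hazard only if the
        # other segments already match; verify via the implied median
        G = postrelapse_survival_implied(solved, tables, np.array([target_median]))
        assert G[0] == pytest.approx(0.5, abs=1e-4)
        # and for a truly constant hazard the exponential median formula
        # holds for the leading segments
        assert solved.post_relapse.rates[0] == pytest.approx(
            np.log(2) / target_median, rel=0.02
        )

    def test_square_system_required(self, tables_s1):
        base = s1_base_scenario()
        with pytest.raises(ScenarioError, match="square"):
            calibrate_scenario(
                [CalibrationTarget("efs", 0.47, time=2.0)],
                base, tables_s1, ["rel_seg0", "exc_early_scale"],
            )

    def test_infeasible_targets_raise(self, tables_s1):
        base = s1_base_scenario()
        # EFS cannot exceed 1 - NRM_pop contribution; an EFS of 99.9% at
        # 10y with the S1 life tables is unreachable with hazards >= 0
        with pytest.raises(ScenarioError, match="binding"):
            calibrate_scenario(
                [CalibrationTarget("efs", 0.999, time=10.0)],
                base, tables_s1, ["rel_seg0"], step=0.01,
            )

    def test_s1_calibration_report(self, s1_report):
        assert s1_report.converged
        assert s1_report.max_abs_residual < 2e-3
        # every printed target is reproduced
        assert len(s1_report.entries) == 15


class TestPostRelapseSurvivalOracle:
    def test_matches_km_after_relapse(self, s1, tables_s1, cohort_100k):
        d = cohort_100k.data
        rel = d["t_relapse"].notna()
        t_pr = np.where(
            d.loc[rel, "t_death"].notna(),
            d.loc[rel, "t_death"] - d.loc[rel, "t_relapse"],
            d.loc[rel, "t_last_fu"] - d.loc[rel, "t_relapse"],
        )
        km = kaplan_meier(t_pr, d.loc[rel, "t_death"].notna().to_numpy())
        u = np.array([0.25, 0.5, 1.0, 2.0])
        G = postrelapse_survival_implied(s1, tables_s1, u)
        for q, g in zip(u, G):
            i = min(np.searchsorted(km.time, q), len(km.variance) - 1)
            se = np.sqrt(max(float(km.variance[i]), 1e-10))
            assert abs(km.at(q) - g) < 4 * se + 2e-3
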