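"""DVH metrics, goal grammar, fractionation scaling and discrepancy counting."""

import numpy as np
import pytest

from dosewarp import (ClinicalGoal, Metric, PrescriptionContext, ScalarVolume,
                      VolumeGrid, eval_goal, eval_metric, goal_discrepancy,
                      load_goal_set, parse_goal, scale_to_course, worst_per_goal)
from dosewarp.dvh import GoalResult
from dosewarp.grid import StructureSet

from oracles import brute_force_volume_fraction, sort_dvh_dose_at_volume


def _uniform_dose(value, n=10, s=2.0):
    grid = VolumeGrid((n, n, n), (s, s, s))
    return ScalarVolume(grid, np.full(grid.size, float(value)), "Gy"), grid


class TestEvalMetric:
    def test_uniform_dose_quantile_and_volume(self):
        dose, grid = _uniform_dose(60.0)
        mask = np.ones(grid.size, bool)
        assert eval_metric(dose, mask, Metric("D_pct", 95)) == pytest.approx(60.0)
        assert eval_metric(dose, mask, Metric("V_Gy", 60)) == pytest.approx(100.0)

    def test_linear_dose_closed_forms(self):
        # dose uniformly distributed over 0..100 Gy: D95% = 5 Gy, V50Gy = 50 %
        n = 4000
        grid = VolumeGrid((n, 1, 1), (1.0, 1.0, 1.0))
        vals = np.linspace(0.0, 100.0, n).reshape(n, 1, 1)
        dose = ScalarVolume(grid, vals, "Gy")
        mask = np.ones(grid.size, bool)
        assert eval_metric(dose, mask, Metric("D_pct", 95)) == pytest.approx(5.0, abs=0.1)
        assert eval_metric(dose, mask, Metric("V_Gy", 50)) == pytest.approx(50.0, abs=0.1)

    def test_near_max_dose_on_uniform_1cc(self):
        # 1 cc structure at uniform 45 Gy: the hottest 0.03 cc gets 45 Gy
        grid = VolumeGrid((10, 10, 10), (1.0, 1.0, 1.0))
        dose = ScalarVolume(grid, np.full(grid.size, 45.0), "Gy")
        mask = np.zeros(grid.size, bool)
        mask[:10, :10, :10] = True  # 1000 voxels x 1 mm^3 = 1 cc
        assert eval_metric(dose, mask, Metric("D_cc", 0.03)) == pytest.approx(45.0)

    def test_matches_full_sort_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        grid = VolumeGrid((32, 32, 32), (1.5, 1.5, 2.0))
        for seed in range(3):
            r = np.random.default_rng(seed)
            vals = r.random(grid.size) * 70.0
            dose = ScalarVolume(grid, vals, "Gy")
            mask = r.random(grid.size) > 0.5
            w_cc = grid.voxel_volume_cc
            inside = vals[mask]
            for v_pct in (2.0, 50.0, 95.0):
                got = eval_metric(dose, mask, Metric("D_pct", v_pct))
                want = sort_dvh_dose_at_volume(inside, v_pct / 100 * inside.size * w_cc, w_cc)
                assert got == pytest.approx(want, abs=0.1)
            for d in (10.0, 35.0, 60.0):
                got = eval_metric(dose, mask, Metric("V_Gy", d))
                assert got == pytest.approx(brute_force_volume_fraction(inside, d), abs=0.1)

    def test_volume_metric_monotone_and_coverage_limits(self):
        rng = np.random.default_rng(1)
        grid = VolumeGrid((16, 16, 16), (2.0, 2.0, 2.0))
        dose = ScalarVolume(grid, rng.random(grid.size) * 50, "Gy")
        mask = np.ones(grid.size, bool)
        vols = [eval_metric(dose, mask, Metric("V_Gy", d)) for d in (5, 15, 25, 45)]
        assert all(a >= b for a, b in zip(vols, vols[1:]))
        assert eval_metric(dose, mask, Metric("D_pct", 100)) == pytest.approx(
            dose.values.min(), abs=0.05)

    def test_empty_mask_and_oversized_volume_rejected(self):
        dose, grid = _uniform_dose(10.0)
        with pytest.raises(ValueError, match="empty"):
            eval_metric(dose, np.zeros(grid.size, bool), Metric("D_pct", 95))
        small = np.zeros(grid.size, bool)
        small[0, 0, 0] = True
        with pytest.raises(ValueError, match="exceeds"):
            eval_metric(dose, small, Metric("D_cc", 5000.0))


class TestGoalGrammar:
    def test_parse_relative_dose_goal_with_variation(self):
        g = parse_goal("CTV", "D0.03cc < 105% (109%)")
        assert g.metric == Metric("D_cc", 0.03)
        assert g.direction == "less_than"
        assert (g.threshold, g.threshold_unit, g.variation) == (105.0, "%", 109.0)
        assert g.report_unit == "Gy"

    def test_parse_volume_goals(self):
        g = parse_goal("rectum", "V60Gy < 3% (10%)")
        assert g.metric == Metric("V_Gy", 60.0)
        assert g.report_unit == "%"
        g2 = parse_goal("bowel", "V45Gy < 50cc")
        assert g2.report_unit == "cc"
        assert g2.variation is None

    def test_parse_spaced_absolute_goal(self):
        g = parse_goal("rectum", "V52.8 Gy < 20% (30%)")
        assert g.metric.param == pytest.approx(52.8)
        g2 = parse_goal("rectum", "D0.03cc < 62.4 Gy (64.2 Gy)")
        assert (g2.threshold, g2.threshold_unit, g2.variation) == (62.4, "Gy", 64.2)

    def test_malformed_goal_rejected(self):
        with pytest.raises(ValueError):
            parse_goal("CTV", "Dmax is small")

    def test_builtin_goal_sets_load(self):
        assert len(load_goal_set("prostate_like")) == 22
        assert len(load_goal_set("cervix_like")) == 21


class TestEvalGoal:
    def _ctx(self, dose_val=60.0):
        dose, grid = _uniform_dose(dose_val)
        ss = StructureSet(grid, {"CTV": np.ones(grid.size, bool)})
        rx = PrescriptionContext(60.0, 20)
        return dose, ss, rx

    def test_strict_inequality_ties_fail(self):
        dose, ss, rx = self._ctx(60.0)
        g = parse_goal("CTV", "D95% > 100%")
        r = eval_goal(g, dose, ss, rx)
        assert r.value == pytest.approx(60.0)
        assert not r.met  # exactly at threshold: strict '>' fails

    def test_failed_goal_within_variation(self):
        dose, ss, rx = self._ctx(60.0)
        # uniform 60 Gy: V60Gy = 100 % -> fails "< 3 %" but variation at 101 % holds
        g = ClinicalGoal("CTV", Metric("V_Gy", 60.0), "less_than", 3.0, "%",
                         variation=101.0)
        r = eval_goal(g, dose, ss, rx)
        assert not r.met and r.within_variation

    def test_absolute_cc_goal(self):
        dose, grid = _uniform_dose(60.0, n=10, s=2.0)  # voxel 8 mm^3
        ss = StructureSet(grid, {"bowel": np.ones(grid.size, bool)})
        rx = PrescriptionContext(45.0, 25)
        g = parse_goal("bowel", "V45Gy < 50cc")
        r = eval_goal(g, dose, ss, rx)
        # 1000 voxels x 0.008 cc all >= 45 Gy -> 8 cc? no: 8000 mm^3 = 8 cc
        assert r.value == pytest.approx(8.0)
        assert r.met

    def test_unknown_structure_rejected(self):
        dose, ss, rx = self._ctx()
        with pytest.raises(KeyError):
            eval_goal(parse_goal("spleen", "D95% > 100%"), dose, ss, rx)


class TestScaling:
    def test_identity_for_single_fraction(self):
        dose, _ = _uniform_dose(2.5)
        assert np.array_equal(scale_to_course(dose, 1).values, dose.values)

    @pytest.mark.parametrize("per_fx,n,total", [(3.0, 20, 60.0), (1.8, 25, 45.0)])
    def test_course_totals(self, per_fx, n, total):
        dose, _ = _uniform_dose(per_fx)
        out = scale_to_course(dose, n)
        assert np.allclose(out.values, total)


def _bool_results(flags):
    return [list(map(bool, fx)) for fx in flags]


class TestDiscrepancy:
    @pytest.mark.parametrize("G,F,a,b,expected", [
        (22, 9, 7, 3, 5),
        (22, 9, 10, 0, 5),
        (21, 11, 19, 2, 9),
        (21, 11, 5, 6, 5),
        (10, 4, 0, 0, 0),
    ])
    def test_integer_percentage(self, G, F, a, b, expected):
        rng = np.random.default_rng(G * F + a + b)
        truth = rng.random((F, G)) > 0.5
        sys = truth.copy()
        flat = [(f, g) for f in range(F) for g in range(G)]
        rng.shuffle(flat)
        for f, g in flat[:a]:
            sys[f, g], truth[f, g] = True, False
        for f, g in flat[a:a + b]:
            sys[f, g], truth[f, g] = False, True
        s = goal_discrepancy(_bool_results(sys), _bool_results(truth))
        assert (s.passed_sys_failed_true, s.failed_sys_passed_true) == (a, b)
        assert s.percentage == expected

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        sys = rng.random((5, 8)) > 0.4
        truth = rng.random((5, 8)) > 0.4
        s1 = goal_discrepancy(_bool_results(sys), _bool_results(truth))
        perm = rng.permutation(5)
        s2 = goal_discrepancy(_bool_results(sys[perm]), _bool_results(truth[perm]))
        assert s1.percentage == s2.percentage

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            goal_discrepancy([[True]], [[True], [False]])


class TestWorstPerGoal:
    def _results(self, direction, values_per_fx):
        goal = ClinicalGoal("CTV", Metric("V_Gy", 60.0), direction, 5.0, "%")
        return [[GoalResult(goal, v, True, True)] for v in values_per_fx]

    def test_single_fraction_is_its_own_worst(self):
        assert worst_per_goal(self._results("less_than", [4.2])) == [4.2]

    def test_less_than_goal_takes_max(self):
        assert worst_per_goal(self._results("less_than", [5, 7, 6])) == [7]

    def test_greater_than_goal_takes_min(self):
        assert worst_per_goal(self._results("greater_than", [59.7, 57.9])) == [57.9]
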