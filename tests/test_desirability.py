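"""Desirability transforms, composites, and the cube optimizer."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromopt import (
    DesirabilityGoal,
    composite,
    d_individual,
    observed_range_goals,
    optimize,
    threshold_goals,
)
from chromopt.rsm import QuadraticModel

unit = st.floats(0.001, 1.0, allow_nan=False)


def goal(direction="maximize", low=0.0, high=1.0, **kw):
    return DesirabilityGoal("y", direction, low, high, **kw)


class TestIndividual:
    def test_maximize_anchors_and_midpoint(self):
        g = goal(low=1.0, high=3.0)
        assert d_individual(1.0, g) == 0.0
        assert d_individual(3.0, g) == 1.0
        assert d_individual(2.0, g) == pytest.approx(0.5)
        assert d_individual(0.5, g) == 0.0
        assert d_individual(5.0, g) == 1.0

    def test_minimize_mirrors_maximize(self):
        g_max = goal("maximize", 1.0, 3.0)
        g_min = goal("minimize", 1.0, 3.0)
        for y in np.linspace(0.5, 3.5, 13):
            assert d_individual(y, g_min) == pytest.approx(
                d_individual(4.0 - y, g_max)
            )

    def test_target_ramp_peaks_at_target(self):
        g = goal("target", 0.0, 10.0, target=4.0)
        assert d_individual(4.0, g) == 1.0
        assert d_individual(2.0, g) == pytest.approx(0.5)
        assert d_individual(7.0, g) == pytest.approx(0.5)
        assert d_individual(0.0, g) == 0.0
        assert d_individual(10.0, g) == 0.0

    def test_shape_exponent_bends_the_ramp(self):
        g = goal(shape=2.0)
        assert d_individual(0.5, g) == pytest.approx(0.25)

    def test_inverted_anchors_rejected(self):
        with pytest.raises(ValueError):
            goal(low=3.0, high=1.0)

    @given(y=st.floats(-5, 5, allow_nan=False))
    def test_always_in_unit_interval(self, y):
        for g in (goal(), goal("minimize"), goal("target", -1.0, 2.0, target=0.5)):
            assert 0.0 <= d_individual(y, g) <= 1.0


class TestComposite:
    def test_all_ones_give_one(self):
        assert composite([1, 1, 1], [3, 3, 1]) == 1.0

    def test_any_zero_annihilates(self):
        assert composite([0.9, 0.0, 1.0], [1, 3, 5]) == 0.0

    def test_weighted_hand_example(self):
        # (0.25^1 * 1^3)^(1/4)
        assert composite([0.25, 1.0], [1, 3]) == pytest.approx(0.25 ** 0.25)

    @given(d=st.lists(unit, min_size=1, max_size=6))
    def test_bounded_by_extremes(self, d):
        w = [3] * len(d)
        D = composite(d, w)
        assert min(d) - 1e-12 <= D <= max(d) + 1e-12

    @given(dcommon=unit, w=st.lists(st.integers(1, 5), min_size=1, max_size=6))
    def test_equal_desirabilities_pass_through_any_impacts(self, dcommon, w):
        assert composite([dcommon] * len(w), w) == pytest.approx(dcommon)

    @given(d=st.lists(unit, min_size=2, max_size=5), bump=unit)
    def test_monotone_in_each_component(self, d, bump):
        w = [2] * len(d)
        d2 = list(d)
        d2[0] = min(1.0, d2[0] + bump)
        assert composite(d2, w) >= composite(d, w) - 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            composite([], [])


def _model_from(coef, name="y"):
    return QuadraticModel.from_coefficients(name, coef)


class TestOptimize:
    def test_concave_quadratic_vertex_recovered(self):
        # y = 5 - (x1-0.3)^2 - (x2+0.2)^2 - (x3-0.5)^2, vertex inside cube
        coef = np.array(
            [5 - 0.09 - 0.04 - 0.25, 0.6, -0.4, 1.0, -1, 0, 0, -1, 0, -1]
        )
        m = _model_from(coef)
        g = [DesirabilityGoal("y", "maximize", 0.0, 5.0)]
        res = optimize([m], g, grid_n=41)
        assert np.allclose(res.coded_optimum, (0.3, -0.2, 0.5), atol=1e-4)

    def test_constant_models_tie_break_to_lexicographic_smallest(self):
        m = _model_from(np.array([0.5] + [0.0] * 9))
        g = [DesirabilityGoal("y", "maximize", 0.0, 1.0)]
        res = optimize([m], g, grid_n=11)
        assert res.coded_optimum == (-1.0, -1.0, -1.0)
        assert res.composite_D == pytest.approx(0.5)

    def test_all_zero_surface_is_flagged(self):
        m = _model_from(np.array([-1.0] + [0.0] * 9))
        g = [DesirabilityGoal("y", "maximize", 0.0, 1.0)]
        res = optimize([m], g, grid_n=11)
        assert res.all_zero
        assert res.composite_D == 0.0

    def test_grid_refinement_converges(self):
        coef = np.array([2.0, 0.8, -0.3, 0.5, -1.2, 0.1, 0.0, -0.9, 0.2, -1.5])
        m = _model_from(coef)
        g = [DesirabilityGoal("y", "maximize", 0.0, 3.0)]
        coarse = optimize([m], g, grid_n=21)
        fine = optimize([m], g, grid_n=42)
        spacing = 2.0 / 20
        dev = np.abs(
            np.array(coarse.coded_optimum) - np.array(fine.coded_optimum)
        )
        assert (dev < spacing).all()

    def test_goal_model_mismatch_rejected(self):
        m = _model_from(np.zeros(10), "a")
        g = [DesirabilityGoal("b", "maximize", 0.0, 1.0)]
        with pytest.raises(ValueError, match="matches no model"):
            optimize([m], g)


class TestStudyOptimum:
    def test_interior_optimum_near_reported_conditions(
        self, study_models, study_table, study_factors
    ):
        # threshold-anchored goals (Rs ramps 0 -> 1.5, time minimized over
        # its observed range) place the optimum within 0.15 coded units of
        # the study's reported (0.69, 0.49, 0.88) on every axis
        goals = threshold_goals(study_table.columns, table=study_table)
        res = optimize(study_models, goals, grid_n=201, factors=study_factors)
        assert all(-1 < v < 1 for v in res.coded_optimum)
        dev = np.abs(np.array(res.coded_optimum) - np.array([0.69, 0.49, 0.88]))
        assert (dev <= 0.15).all(), dev
        assert 0 < res.composite_D <= 1

    def test_observed_range_anchoring_drives_x1_to_boundary(
        self, study_models, study_table
    ):
        # documents why observed-range anchoring is not the default here:
        # rewarding ever-larger resolutions pushes %B initial to the edge
        goals = observed_range_goals(study_table.columns, study_table)
        res = optimize(study_models, goals, grid_n=61)
        assert res.coded_optimum[0] == pytest.approx(1.0, abs=1e-6)

    def test_goal_builders_set_study_impacts(self, study_table):
        goals = threshold_goals(study_table.columns, table=study_table)
        by = {g.response_name: g for g in goals}
        assert all(by[c].impact == 3 for c in study_table.columns if c.startswith("Rs"))
        assert by["time_min"].impact == 1
        assert by["time_min"].direction == "minimize"
        assert by["time_min"].low == pytest.approx(14.7)
        assert by["time_min"].high == pytest.approx(25.4)
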