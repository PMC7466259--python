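"""Second-order model fitting: OLS correctness, inference and reduction."""

import numpy as np
import pytest

from chromopt import build_bbd, fit_full_quadratic, reduce_model
from chromopt.rsm import TERM_NAMES, design_matrix
from conftest import random_bbd_dataset


def normal_equations_ols(X, y):
    """Independent oracle: solve X'X b = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFitCorrectness:
    def test_noise_free_quadratic_recovered_exactly(self, study_factors):
        rng = np.random.default_rng(0)
        design = build_bbd(study_factors, n_center=3)
        beta = rng.normal(0, 2, 10)
        y = design_matrix(design.coded_matrix()) @ beta
        m = fit_full_quadratic(design, y)
        assert np.allclose(m.coef, beta, atol=1e-9)
        assert m.r2 == pytest.approx(1.0)
        assert m.degenerate

    def test_matches_normal_equations_oracle(self, study_factors):
        rng = np.random.default_rng(1)
        for _ in range(20):
            design, y = random_bbd_dataset(rng, study_factors)
            m = fit_full_quadratic(design, y)
            X = design_matrix(design.coded_matrix())
            assert np.allclose(m.coef, normal_equations_ols(X, y), atol=1e-9)

    def test_intercept_equals_center_mean_on_random_data(self, study_factors):
        # the center-run indicator 1 - (x1^2+x2^2+x3^2)/2 lies in the model
        # span, so the OLS intercept is the center mean for any BBD data
        rng = np.random.default_rng(2)
        for _ in range(100):
            design, y = random_bbd_dataset(rng, study_factors)
            m = fit_full_quadratic(design, y)
            center = [i for i, p in enumerate(design.points) if p.is_center]
            assert m.beta0 == pytest.approx(np.mean(y[center]), abs=1e-9)

    def test_fit_invariant_to_row_permutation(self, study_factors):
        rng = np.random.default_rng(3)
        design, y = random_bbd_dataset(rng, study_factors)
        m = fit_full_quadratic(design, y)
        perm = rng.permutation(design.n_runs)
        from chromopt.doe import Design, DesignPoint

        shuffled = Design(
            factors=design.factors,
            points=[
                DesignPoint(run_id=i + 1, coded=design.points[j].coded)
                for i, j in enumerate(perm)
            ],
            n_center=design.n_center,
        )
        m2 = fit_full_quadratic(shuffled, y[perm])
        assert np.allclose(m.coef, m2.coef, atol=1e-10)
        assert m2.r2 == pytest.approx(m.r2)

    def test_length_mismatch_rejected(self, canonical_design):
        with pytest.raises(ValueError, match="length"):
            fit_full_quadratic(canonical_design, np.ones(12))

    def test_too_few_observations_rejected(self, study_factors):
        d = build_bbd(study_factors, n_center=0)
        d.points = d.points[:10]
        with pytest.raises(ValueError):
            fit_full_quadratic(d, np.ones(10))


class TestStudyRefits:
    @pytest.mark.parametrize(
        "response,constant",
        [("Rs1-2", 3.092), ("Rs2-3", 1.297), ("Rs3-4", 0.848),
         ("Rs4-5", 2.594), ("Rs5-6", 0.000), ("Rs6-7", 1.275),
         ("Rs7-8", 0.877)],
    )
    def test_reported_constants_reproduced(self, study_models, response, constant):
        m = {x.response_name: x for x in study_models}[response]
        assert round(m.beta0, 3) == pytest.approx(constant, abs=5e-4)

    def test_rs45_constant_is_center_mean(self, study_models):
        m = {x.response_name: x for x in study_models}["Rs4-5"]
        assert m.beta0 == pytest.approx((2.6014 + 2.6402 + 2.5400) / 3, abs=1e-9)

    def test_rs56_constant_zero_validates_fop_encoding(self, study_models):
        # the three center cells of Rs5-6 are FOP markers; their encoded
        # mean (0) must equal the intercept, matching the reported 0.000
        m = {x.response_name: x for x in study_models}["Rs5-6"]
        assert m.beta0 == pytest.approx(0.0, abs=1e-12)

    def test_analysis_time_constant_is_center_mean_not_reported_value(
        self, study_models
    ):
        # the reported 23.085 cannot arise from any OLS fit of this table:
        # the intercept is pinned to the center mean 17.833
        m = {x.response_name: x for x in study_models}["time_min"]
        assert m.beta0 == pytest.approx(17.8333, abs=1e-3)

    def test_rs34_r2_matches_reported(self, study_models):
        m = {x.response_name: x for x in study_models}["Rs3-4"]
        assert m.r2 == pytest.approx(0.7414, abs=5e-4)

    def test_rs23_significant_terms_are_pH_and_pH_squared(self, study_models):
        m = {x.response_name: x for x in study_models}["Rs2-3"]
        assert set(m.significant_terms(0.05)) == {"x3", "x3x3"}

    def test_predict_at_center_returns_constant(self, study_models):
        for m in study_models:
            assert m.predict((0, 0, 0)) == pytest.approx(m.beta0)

    def test_rs45_center_prediction(self, study_models):
        m = {x.response_name: x for x in study_models}["Rs4-5"]
        assert round(m.predict((0.0, 0.0, 0.0)), 3) == 2.594

    def test_adjusted_r2_never_exceeds_r2(self, study_models):
        for m in study_models:
            assert m.r2_adj <= m.r2 + 1e-12
            assert m.p_values is not None
            assert ((m.p_values >= 0) & (m.p_values <= 1)).all()


class TestInference:
    def test_constructed_single_active_term_flagged(self, study_factors):
        rng = np.random.default_rng(4)
        design = build_bbd(study_factors, n_center=3)
        X = design_matrix(design.coded_matrix())
        y = 2.0 * X[:, TERM_NAMES.index("x3")] + rng.normal(0, 0.01, 15)
        m = fit_full_quadratic(design, y)
        assert "x3" in m.significant_terms(0.05)
        others = set(m.significant_terms(0.05)) - {"x3"}
        assert not others

    def test_degenerate_fit_reports_zero_pvalues(self, study_factors):
        design = build_bbd(study_factors, n_center=3)
        y = design_matrix(design.coded_matrix()) @ np.arange(10, dtype=float)
        m = fit_full_quadratic(design, y)
        assert m.degenerate
        assert (m.p_values[np.abs(m.coef) > 0] == 0).all()


class TestReduction:
    def test_rs12_reduces_to_intercept_plus_pH_squared(
        self, study_models, study_design, study_table
    ):
        m = {x.response_name: x for x in study_models}["Rs1-2"]
        red = reduce_model(m, study_design, study_table.column("Rs1-2"), alpha=0.05)
        assert set(red.terms) == {"constant", "x3x3"}

    def test_alpha_one_returns_full_model(self, study_models, study_design, study_table):
        m = study_models[0]
        red = reduce_model(m, study_design, study_table.column(m.response_name), alpha=1.0)
        assert red is m

    def test_reduction_never_increases_r2(self, study_models, study_design, study_table):
        for m in study_models:
            red = reduce_model(
                m, study_design, study_table.column(m.response_name), alpha=0.05
            )
            assert red.r2 <= m.r2 + 1e-12

    def test_all_terms_survive_on_noise_free_full_signal(self, study_factors):
        design = build_bbd(study_factors, n_center=3)
        rng = np.random.default_rng(8)
        beta = rng.uniform(1, 2, 10) * np.sign(rng.normal(size=10))
        y = design_matrix(design.coded_matrix()) @ beta + rng.normal(0, 1e-8, 15)
        m = fit_full_quadratic(design, y)
        red = reduce_model(m, design, y, alpha=0.05)
        assert set(red.terms) == set(TERM_NAMES)
        assert np.allclose(red.coef_full(), m.coef_full(), atol=1e-6)
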