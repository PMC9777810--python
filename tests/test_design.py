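"""CCC design construction, coding transforms, polynomial fitting and reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrokin import (
    SQRT2,
    ResponseSurface,
    VariableCoding,
    anova,
    build_ccc,
    design_matrix,
    fit_polynomial,
    fixed_b,
    reduce_model,
)
from hydrokin.datasets import (
    PROTEASES,
    load_kinetic_constants,
    reduced_model_terms,
    study_design,
    variable_codings,
)
from hydrokin.exceptions import InputDataError

# Published reduced-model coefficients (term -> value) for each protease and
# constant, as printed in the study's regression tables.
PUBLISHED_COEFFICIENTS = {
    ("alcalase", "a"): {"1": 9.694, "x1": 4.563, "x2": 4.880, "x1*x2": 2.820},
    ("alcalase", "b"): {"1": 0.04103, "x1": -0.00537, "x2": -0.00344},
    ("neutrase", "a"): {"1": 25.07, "x1": 22.86, "x2": 17.41, "x1^2": 17.49},
    ("neutrase", "b"): {"1": 0.08091, "x1": -0.01352, "x1^2": 0.01470},
    ("protamex", "a"): {"1": 17.25, "x1": 7.40, "x2": 9.60, "x1*x2": 4.79},
    ("protamex", "b"): {"1": 0.0423, "x1": -0.00731, "x1^2": 0.00436},
}


class TestBuildCCC:
    def test_reproduces_study_design_as_a_set(self):
        built = build_ccc(n_center=2)
        study = study_design()
        built_set = {tuple(np.round(r, 10)) for r in built.coded}
        study_set = {tuple(np.round(r, 10)) for r in study.coded}
        assert built_set == study_set
        assert built.n_runs == 10

    def test_center_count(self):
        assert build_ccc(n_center=1).n_runs == 9

    def test_odd_columns_sum_to_zero(self):
        x = build_ccc(n_center=3).coded
        assert np.sum(x[:, 0]) == pytest.approx(0.0, abs=1e-12)
        assert np.sum(x[:, 1]) == pytest.approx(0.0, abs=1e-12)
        assert np.sum(x[:, 0] * x[:, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_requires_a_center_point(self):
        with pytest.raises(InputDataError):
            build_ccc(n_center=0)


class TestVariableCoding:
    def test_temperature_levels(self):
        coding = variable_codings()["T"]
        assert coding.decode(-SQRT2) == pytest.approx(47.93, abs=0.01)
        assert coding.decode(0.0) == 55.0
        np.testing.assert_allclose(
            coding.levels(), [47.93, 50, 55, 60, 62.07], atol=0.01
        )

    def test_dose_level(self):
        coding = variable_codings()["E"]
        assert coding.decode(1.0) == 200.0

    @settings(derandomize=True, max_examples=50)
    @given(x=st.floats(min_value=-3, max_value=3, allow_nan=False))
    def test_encode_decode_round_trip(self, x):
        coding = VariableCoding(name="T", center=55.0, step=5.0)
        assert coding.encode(coding.decode(x)) == pytest.approx(x, abs=1e-12)


class TestFitPolynomial:
    def test_intercept_is_mean_without_quadratic_terms(self, design_points, rng):
        y = rng.normal(10.0, 2.0, size=10)
        res = fit_polynomial(design_points, y, ("1", "x1", "x2", "x1*x2"))
        assert res.params["1"] == pytest.approx(y.mean(), rel=1e-12)

    def test_closed_form_coefficients_on_orthogonal_design(self, design_points, rng):
        """beta_j = sum(x_j*y)/sum(x_j^2) for x1, x2 and x1*x2 on this design."""
        y = rng.normal(0.0, 1.0, size=10)
        res = fit_polynomial(design_points, y, ("1", "x1", "x2", "x1*x2"))
        x1, x2 = design_points[:, 0], design_points[:, 1]
        for term, col in (("x1", x1), ("x2", x2), ("x1*x2", x1 * x2)):
            closed = np.sum(col * y) / np.sum(col**2)
            assert res.params[term] == pytest.approx(closed, abs=1e-10)

    @pytest.mark.parametrize("protease,constant", PUBLISHED_COEFFICIENTS)
    def test_reproduces_published_coefficients(self, protease, constant, design_points):
        """Refitting the published per-run constants recovers every printed
        coefficient of the reduced models within 2% (inputs rounded to 3 s.f.)."""
        table = load_kinetic_constants(protease)
        res = fit_polynomial(
            design_points, table[constant], reduced_model_terms(protease, constant)
        )
        for term, ref in PUBLISHED_COEFFICIENTS[(protease, constant)].items():
            assert res.params[term] == pytest.approx(ref, rel=0.02), (protease, constant, term)

    def test_singular_design_names_collinear_terms(self):
        points = np.column_stack([np.linspace(-1, 1, 8), np.linspace(-1, 1, 8)])
        with pytest.raises(InputDataError, match="x2"):
            ResponseSurface(points, np.arange(8.0), ("1", "x1", "x2"))

    def test_response_length_checked(self, design_points):
        with pytest.raises(InputDataError):
            fit_polynomial(design_points, np.arange(9.0))


class TestReduceModel:
    def test_single_pass_recovers_published_interaction_models(self, design_points):
        """Dropping all non-significant full-model terms at once yields the
        published supports for the Alcalase and Protamex initial-rate models."""
        for protease in ("alcalase", "protamex"):
            y = load_kinetic_constants(protease)["a"]
            res = reduce_model(design_points, y, alpha=0.05, method="single_pass")
            assert set(res.terms) == set(reduced_model_terms(protease, "a"))

    def test_backward_recovers_published_neutrase_quadratic(self, design_points):
        y = load_kinetic_constants("neutrase")["a"]
        res = reduce_model(design_points, y, alpha=0.05)
        assert set(res.terms) == set(reduced_model_terms("neutrase", "a"))

    @pytest.mark.parametrize("method", ["backward", "single_pass"])
    @pytest.mark.parametrize("protease", PROTEASES)
    def test_extension_constant_models(self, protease, method, design_points):
        """Both elimination rules agree on the published b-model supports."""
        y = load_kinetic_constants(protease)["b"]
        res = reduce_model(design_points, y, alpha=0.05, method=method)
        assert set(res.terms) == set(reduced_model_terms(protease, "b"))

    @pytest.mark.parametrize("method", ["backward", "single_pass"])
    def test_idempotent(self, method, design_points):
        y = load_kinetic_constants("alcalase")["a"]
        once = reduce_model(design_points, y, alpha=0.05, method=method)
        twice = once.reduce(alpha=0.05, method=method)
        assert twice.terms == once.terms
        np.testing.assert_allclose(twice.params, once.params)

    def test_pure_noise_retention_matches_test_size(self, design_points):
        """Under the null, elimination controls each term at roughly the 5%
        level: per-term retention stays near alpha, and the family-wise
        retention of any term stays near 1-(1-alpha)^5 (about 23%), so the
        intercept-only model dominates."""
        from collections import Counter

        retained = Counter()
        intercept_only = 0
        for seed in range(100):
            y = np.random.default_rng(seed).normal(size=10)
            res = reduce_model(design_points, y, alpha=0.05)
            intercept_only += res.terms == ("1",)
            for t in res.terms:
                if t != "1":
                    retained[t] += 1
        # per-term size: binomial(100, ~0.05) stays below 13 with prob > 0.999
        assert all(count <= 13 for count in retained.values()), retained
        assert intercept_only >= 65

    def test_known_surface_support_selection(self, design_points):
        """With unbiased Gaussian noise at a second-level R^2 near 0.97 the
        true terms are always retained and the exact support is recovered at
        close to the theoretical (1-alpha)^2 rate."""
        truth = {"1": 9.69, "x1": 4.56, "x2": 4.88, "x1*x2": 2.82}
        X = design_matrix(design_points, tuple(truth))
        y0 = X @ np.array(list(truth.values()))
        sigma = np.sqrt(np.var(y0) * 0.03 / 0.97)
        exact = 0
        for seed in range(100):
            y = y0 + np.random.default_rng(seed).normal(0.0, sigma, 10)
            res = reduce_model(design_points, y, alpha=0.05)
            assert set(truth) <= set(res.terms)  # true terms never lost
            exact += set(res.terms) == set(truth)
        assert exact >= 85


class TestAnova:
    def test_df_conventions(self, design_points):
        y = load_kinetic_constants("alcalase")["a"]
        res = fit_polynomial(design_points, y, reduced_model_terms("alcalase", "a"))
        assert anova(res, "paper")["df"].tolist() == [4, 5, 9]
        assert anova(res, "standard")["df"].tolist() == [3, 6, 9]

    def test_sum_of_squares_identity(self, design_points, rng):
        y = rng.normal(5.0, 2.0, 10)
        res = fit_polynomial(design_points, y)
        table = res.anova()
        assert table.loc["total", "sum_sq"] == pytest.approx(
            table.loc["regression", "sum_sq"] + table.loc["error", "sum_sq"], rel=1e-8
        )

    def test_published_alcalase_anova_block(self, design_points):
        """Paper-convention mean squares and F for the Alcalase a-model match
        the printed ANOVA within the rounding of the inputs."""
        y = load_kinetic_constants("alcalase")["a"]
        res = fit_polynomial(design_points, y, reduced_model_terms("alcalase", "a"))
        table = anova(res, "paper")
        assert table.loc["regression", "sum_sq"] == pytest.approx(388.86, rel=0.01)
        assert table.loc["regression", "F"] == pytest.approx(66.04, rel=0.03)

    def test_unknown_convention_rejected(self, design_points):
        res = fit_polynomial(design_points, np.arange(10.0))
        with pytest.raises(InputDataError):
            res.anova("bayesian")


class TestFixedB:
    def test_alcalase_center_value(self, design_points):
        b = load_kinetic_constants("alcalase")["b"]
        res = reduce_model(design_points, b, alpha=0.05)
        assert fixed_b(res) == pytest.approx(0.0410, rel=0.01)
        # linear/interaction-only model: center value == plain mean
        assert fixed_b(res) == pytest.approx(fixed_b(b.to_numpy()), rel=1e-10)

    def test_protamex_quadratic_model_center_value(self, design_points):
        b = load_kinetic_constants("protamex")["b"]
        res = fit_polynomial(design_points, b, reduced_model_terms("protamex", "b"))
        assert fixed_b(res) == pytest.approx(0.0423, rel=0.01)

    def test_constant_vector(self):
        assert fixed_b(np.full(10, 0.07)) == pytest.approx(0.07)
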