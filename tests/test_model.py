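import numpy as np
import pandas as pd
import pytest

from multireri import (
    CoefficientSet,
    conditional_reri,
    delta_ci,
    finite_difference_gradient,
    fit_saturated_model,
    measure_gradient,
    read_coefficients,
    reri_top,
    rr_grid_from_coefficients,
    term_ratio_ci,
    tot_reri,
    write_coefficients,
)
from multireri.exceptions import (
    IncompleteModelError,
    MissingVarianceError,
    SpecificationError,
    UnidentifiableCellError,
)
from multireri.grid import canonical_masks
from multireri.measures import MeasureKind, MeasureSpec
from multireri.simulate import default_scenario, generate_cohort

from conftest import PRINTED_HRS


class TestCoefficientSet:
    def test_term_order_is_by_size_then_position(self, worked_coefs):
        assert worked_coefs.term_names == (
            "low_MD",
            "high_BMI",
            "smoker",
            "low_MD*high_BMI",
            "low_MD*smoker",
            "high_BMI*smoker",
            "low_MD*high_BMI*smoker",
        )

    def test_missing_term_rejected(self):
        with pytest.raises(IncompleteModelError):
            CoefficientSet.from_terms({"A": 0.1, "B": 0.2}, factor_names=["A", "B"])

    def test_asymmetric_vcov_rejected(self):
        v = np.array([[1.0, 0.5, 0.0], [0.1, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(SpecificationError):
            CoefficientSet.from_terms(
                {"A": 0.1, "B": 0.2, "A*B": 0.0}, vcov=v, factor_names=["A", "B"]
            )

    def test_negative_variance_rejected(self):
        v = np.diag([1.0, -0.1, 1.0])
        with pytest.raises(SpecificationError):
            CoefficientSet.from_terms(
                {"A": 0.1, "B": 0.2, "A*B": 0.0}, vcov=v, factor_names=["A", "B"]
            )

    def test_file_round_trip(self, tmp_path, worked_coefs):
        coefs = tmp_path / "coefs.tsv"
        vcov = tmp_path / "vcov.tsv"
        write_coefficients(worked_coefs, coefs, vcov_path=vcov)
        back = read_coefficients(coefs, vcov_path=vcov)
        assert back.term_names == worked_coefs.term_names
        assert np.allclose(back.beta, worked_coefs.beta)
        assert np.allclose(back.vcov, worked_coefs.vcov)

    def test_json_round_trip(self, worked_coefs):
        back = CoefficientSet.from_json(worked_coefs.to_json())
        assert np.allclose(back.beta, worked_coefs.beta)
        assert np.allclose(back.vcov, worked_coefs.vcov)


class TestGridFromCoefficients:
    def test_worked_example_ratios(self, worked_coefs):
        g = rr_grid_from_coefficients(worked_coefs)
        assert g.rr("100") == pytest.approx(np.exp(0.36))
        assert round(g.rr("100"), 2) == PRINTED_HRS["low_MD"]
        # all three present: exp of the sum of all seven coefficients
        assert g.rr("111") == pytest.approx(np.exp(1.24), rel=1e-12)

    def test_null_model_gives_unit_grid(self):
        cs = CoefficientSet.from_terms(
            {"A": 0, "B": 0, "A*B": 0}, factor_names=["A", "B"]
        )
        assert np.all(rr_grid_from_coefficients(cs).values == 1.0)

    def test_log_rr_is_subset_sum(self, worked_coefs):
        g = rr_grid_from_coefficients(worked_coefs)
        n = worked_coefs.n
        for m in canonical_masks(n):
            expected = sum(
                worked_coefs.beta[t]
                for t in worked_coefs.term_masks
                if (t & ~m) == 0
            )
            assert np.log(g.values[m]) == pytest.approx(expected, abs=1e-12)


def _random_coefset(rng, n, with_vcov=False):
    names = [f"X{i + 1}" for i in range(n)]
    masks = [m for m in canonical_masks(n) if m]
    beta = {m: rng.normal(0, 0.5) for m in masks}
    vcov = None
    if with_vcov:
        a = rng.normal(0, 0.1, (len(masks), len(masks)))
        vcov = a @ a.T + 0.01 * np.eye(len(masks))
    return CoefficientSet(names, beta, vcov=vcov)


ALL_KINDS_N3 = [
    MeasureSpec(MeasureKind.TOT_RERI, ("X1", "X2", "X3")),
    MeasureSpec(MeasureKind.RERI_TOP, ("X1", "X2", "X3")),
    MeasureSpec(MeasureKind.CONDITIONAL_RERI, ("X1", "X2"), (("X3", 0),)),
    MeasureSpec(MeasureKind.CONDITIONAL_RERI, ("X1", "X3"), (("X2", 1),)),
    MeasureSpec(MeasureKind.MULT_INDEX, ("X1", "X2", "X3")),
    MeasureSpec(MeasureKind.MULT_INDEX, ("X2", "X3")),
]


class TestGradients:
    def test_product_term_gradient_is_joint_rr(self):
        cs = CoefficientSet.from_terms(
            {"A": np.log(2), "B": np.log(3), "A*B": 0.0}, factor_names=["A", "B"]
        )
        spec = MeasureSpec(MeasureKind.RERI_TOP, ("A", "B"))
        g = measure_gradient(cs, spec)
        # d RERI_2 / d beta_AB = RR_11 = 6
        assert g[list(cs.term_names).index("A*B")] == pytest.approx(6.0)

    def test_null_model_gradient_matches_finite_differences(self):
        cs = CoefficientSet.from_terms(
            {"A": 0, "B": 0, "A*B": 0}, factor_names=["A", "B"]
        )
        spec = MeasureSpec(MeasureKind.RERI_TOP, ("A", "B"))
        g = measure_gradient(cs, spec)
        fd = finite_difference_gradient(cs, spec)
        # at the null model the main-effect derivatives cancel exactly
        assert np.allclose(g, [0.0, 0.0, 1.0], atol=1e-12)
        assert np.allclose(g, fd, atol=1e-6)

    @pytest.mark.parametrize("spec", ALL_KINDS_N3, ids=lambda s: s.label())
    def test_analytic_matches_finite_differences(self, spec):
        rng = np.random.default_rng(11)
        for _ in range(5):
            cs = _random_coefset(rng, 3)
            g = measure_gradient(cs, spec)
            fd = finite_difference_gradient(cs, spec)
            scale = np.maximum(np.abs(fd), 1.0)
            assert np.all(np.abs(g - fd) / scale < 1e-6)


class TestDeltaCI:
    def test_hr_ci_matches_published(self, worked_coefs):
        r = term_ratio_ci(worked_coefs, "low_MD")
        assert (round(r.ci[0], 2), round(r.ci[1], 2)) == (1.20, 1.71)
        assert round(r.ratio, 2) == 1.43

    def test_reri_interval_is_symmetric_on_reri_scale(self):
        rng = np.random.default_rng(5)
        cs = _random_coefset(rng, 3, with_vcov=True)
        m = delta_ci(cs, MeasureSpec(MeasureKind.RERI_TOP, ("X1", "X2", "X3")))
        assert m.ci[1] - m.estimate == pytest.approx(m.estimate - m.ci[0], rel=1e-10)
        from scipy import stats

        z = stats.norm.ppf(0.975)
        assert m.ci[1] - m.ci[0] == pytest.approx(2 * z * m.se, rel=1e-10)

    def test_zero_vcov_degenerate_interval(self):
        cs = CoefficientSet.from_terms(
            {"A": 0.3, "B": 0.2, "A*B": 0.1},
            vcov=np.zeros((3, 3)),
            factor_names=["A", "B"],
        )
        m = delta_ci(cs, MeasureSpec(MeasureKind.RERI_TOP, ("A", "B")))
        assert m.se == 0.0
        assert m.ci == (m.estimate, m.estimate)

    def test_missing_vcov_rejected(self):
        cs = CoefficientSet.from_terms(
            {"A": 0.3, "B": 0.2, "A*B": 0.1}, factor_names=["A", "B"]
        )
        with pytest.raises(MissingVarianceError):
            delta_ci(cs, MeasureSpec(MeasureKind.RERI_TOP, ("A", "B")))

    def test_mult_index_interval_is_log_scale(self):
        rng = np.random.default_rng(9)
        cs = _random_coefset(rng, 2, with_vcov=True)
        m = delta_ci(cs, MeasureSpec(MeasureKind.MULT_INDEX, ("X1", "X2")))
        # log-scale Wald: geometric mean of the bounds is the estimate
        assert np.sqrt(m.ci[0] * m.ci[1]) == pytest.approx(m.estimate, rel=1e-10)


class TestFitSaturatedModel:
    def test_logistic_recovers_generating_coefficients(self):
        cfg = default_scenario(seed=3, n_subjects=50000, n_replicates=1)
        cohort = generate_cohort(cfg, 0)
        fitted = fit_saturated_model(
            cohort, cfg.factor_names, outcome="event", family="logistic"
        )
        cs = fitted.coefficients
        truth = cfg.coefficient_set()
        for t, m in zip(cs.term_names, cs.term_masks):
            assert abs(cs.beta[m] - truth.beta[m]) < 4 * cs.se(t), t

    def test_unobserved_pattern_raises_named_cell(self):
        rng = np.random.default_rng(0)
        n = 500
        df = pd.DataFrame(
            {
                "A": rng.integers(0, 2, n),
                "B": rng.integers(0, 2, n),
                "C": rng.integers(0, 2, n),
                "y": rng.integers(0, 2, n),
            }
        )
        df.loc[(df.A == 1) & (df.B == 1) & (df.C == 1), "A"] = 0  # empty the 111 cell
        with pytest.raises(UnidentifiableCellError) as exc:
            fit_saturated_model(df, ["A", "B", "C"], outcome="y", family="logistic")
        assert exc.value.pattern == "111"

    def test_non_binary_exposure_rejected(self):
        df = pd.DataFrame({"A": [0, 1, 2, 1], "B": [0, 1, 0, 1], "y": [0, 1, 0, 1]})
        with pytest.raises(TypeError):
            fit_saturated_model(df, ["A", "B"], outcome="y", family="logistic")

    def test_missing_column_named(self):
        df = pd.DataFrame({"A": [0, 1], "B": [1, 0]})
        with pytest.raises(SpecificationError, match="outcome"):
            fit_saturated_model(df, ["A", "B"], outcome="outcome", family="logistic")

    def test_cox_and_logistic_agree_on_rare_outcome(self):
        # rare-disease concordance: HR-based and OR-based RERIs should be
        # close when events are uncommon
        cfg = default_scenario(
            seed=8, family="survival", n_subjects=40000, n_replicates=1
        )
        cohort = generate_cohort(cfg, 0)
        cohort["died"] = cohort["event"]
        cox = fit_saturated_model(
            cohort,
            cfg.factor_names,
            time="time",
            event="event",
            family="proportional_hazards",
        )
        logit = fit_saturated_model(
            cohort, cfg.factor_names, outcome="died", family="logistic"
        )
        r_cox = reri_top(rr_grid_from_coefficients(cox.coefficients)).estimate
        r_log = reri_top(rr_grid_from_coefficients(logit.coefficients)).estimate
        se = delta_ci(
            cox.coefficients, MeasureSpec(MeasureKind.RERI_TOP, cfg.factor_names)
        ).se
        assert abs(r_cox - r_log) < 2 * se

    def test_covariates_kept_out_of_grid(self):
        from multireri.simulate import CovariateConfig

        cfg = default_scenario(
            seed=5,
            n_subjects=20000,
            n_replicates=1,
            covariates=CovariateConfig(age_effect=0.02, education_effects=(0.1, 0.2, 0.3)),
        )
        cohort = generate_cohort(cfg, 0)
        fitted = fit_saturated_model(
            cohort,
            cfg.factor_names,
            outcome="event",
            covariates=["age", "education"],
            family="logistic",
        )
        assert fitted.coefficients.n_terms == 7
        assert "age" in fitted.covariate_estimates.index
        assert any(
            name.startswith("education_") for name in fitted.covariate_estimates.index
        )
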