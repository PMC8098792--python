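import numpy as np
import pytest

from multireri import (
    classify,
    conditional_reri,
    decompose,
    make_rr_grid,
    multiplicative_index,
    reri2,
    reri_top,
    tot_reri,
)
from multireri.exceptions import (
    DimensionalityError,
    MeasureKindError,
    SpecificationError,
)
from multireri.measures import InteractionMeasure, MeasureKind

from conftest import PRINTED_RERIS, additive_grid, random_grid

TOY2 = {"10": 2, "01": 3, "11": 6}


class TestReri2:
    def test_superadditive_toy(self):
        assert reri2(make_rr_grid(["A", "B"], TOY2)).estimate == pytest.approx(2.0)

    def test_exactly_additive(self):
        g = make_rr_grid(["A", "B"], {"10": 2, "01": 3, "11": 4})
        assert reri2(g).estimate == pytest.approx(0.0, abs=1e-12)

    def test_null_grid(self):
        g = make_rr_grid(["A", "B"], {"10": 1, "01": 1, "11": 1})
        assert reri2(g).estimate == 0.0

    def test_wrong_dimension(self, worked_grid):
        with pytest.raises(DimensionalityError):
            reri2(worked_grid)


class TestTotReri:
    def test_worked_example(self, worked_grid):
        # recomputed from the published two-decimal coefficients; the
        # published table prints 1.20
        assert tot_reri(worked_grid).estimate == pytest.approx(1.20, abs=0.03)

    def test_additive_three_factor(self):
        g = additive_grid(np.array([1.0, 2.0, 0.5]))
        assert tot_reri(g).estimate == pytest.approx(0.0, abs=1e-12)

    def test_doubling_grid_four_factors(self):
        # RR(S) = 2^|S|: TotRERI_4 = 16 - 4*2 + 3
        g = make_rr_grid(
            ["A", "B", "C", "D"],
            {format(m, "04b")[::-1]: 2.0 ** bin(m).count("1") for m in range(16)},
        )
        assert tot_reri(g).estimate == pytest.approx(11.0)

    def test_single_factor_rejected(self):
        with pytest.raises(DimensionalityError):
            tot_reri(make_rr_grid(["A"], {"1": 2}))


class TestReriTop:
    def test_worked_example(self, worked_grid):
        assert reri_top(worked_grid).estimate == pytest.approx(1.98, abs=0.03)

    def test_doubling_grid_four_factors(self):
        # inclusion-exclusion: 16 - 4*8 + 6*4 - 4*2 + 1
        g = make_rr_grid(
            ["A", "B", "C", "D"],
            {format(m, "04b")[::-1]: 2.0 ** bin(m).count("1") for m in range(16)},
        )
        assert reri_top(g).estimate == pytest.approx(1.0)

    def test_two_factor_reduction(self):
        g = make_rr_grid(["A", "B"], TOY2)
        assert reri_top(g).estimate == reri2(g).estimate == tot_reri(g).estimate


class TestConditionalReri:
    @pytest.mark.parametrize(
        "subset,stratum",
        [
            (("low_MD", "high_BMI"), 0),
            (("low_MD", "high_BMI"), 1),
            (("low_MD", "smoker"), 0),
            (("low_MD", "smoker"), 1),
            (("high_BMI", "smoker"), 0),
            (("high_BMI", "smoker"), 1),
        ],
    )
    def test_worked_example_strata(self, worked_grid, subset, stratum):
        (other,) = set(worked_grid.factor_names) - set(subset)
        m = conditional_reri(worked_grid, subset, {other: stratum})
        assert m.estimate == pytest.approx(PRINTED_RERIS[m.label()], abs=0.03)

    def test_empty_conditioning_is_reri2(self):
        g = make_rr_grid(["A", "B"], TOY2)
        assert conditional_reri(g, ("A", "B"), {}).estimate == reri2(g).estimate

    def test_overlapping_subset_and_conditioning(self, worked_grid):
        with pytest.raises(SpecificationError):
            conditional_reri(worked_grid, ("low_MD", "high_BMI"), {"high_BMI": 1})

    def test_incomplete_conditioning(self, worked_grid):
        with pytest.raises(SpecificationError):
            conditional_reri(worked_grid, ("low_MD", "high_BMI"), {})


class TestDecompose:
    def test_worked_example_components(self, worked_grid):
        parts = decompose(worked_grid)
        assert [p.label() for p in parts] == [
            "RERI_3(low_MD,high_BMI,smoker)",
            "RERI_2(low_MD,high_BMI | smoker=0)",
            "RERI_2(low_MD,smoker | high_BMI=0)",
            "RERI_2(high_BMI,smoker | low_MD=0)",
        ]
        total = sum(p.estimate for p in parts)
        assert total == pytest.approx(tot_reri(worked_grid).estimate, rel=1e-10)
        for p in parts:
            assert p.estimate == pytest.approx(PRINTED_RERIS[p.label()], abs=0.03)

    def test_additive_grid_all_zero(self):
        g = additive_grid(np.array([1.0, 2.0, 0.5]))
        for p in decompose(g):
            assert p.estimate == pytest.approx(0.0, abs=1e-12)

    def test_four_factor_component_count_and_sum(self):
        rng = np.random.default_rng(42)
        g = random_grid(rng, 4)
        parts = decompose(g)
        assert len(parts) == 1 + 4 + 6  # top + C(4,3) + C(4,2)
        assert sum(p.estimate for p in parts) == pytest.approx(
            tot_reri(g).estimate, rel=1e-10
        )


class TestMultiplicativeIndex:
    def test_exactly_multiplicative(self):
        assert multiplicative_index(make_rr_grid(["A", "B"], TOY2)).estimate == 1.0

    def test_supermultiplicative(self):
        g = make_rr_grid(["A", "B"], {"10": 2, "01": 3, "11": 12})
        assert multiplicative_index(g).estimate == pytest.approx(2.0)

    def test_null_grid(self):
        g = make_rr_grid(["A", "B"], {"10": 1, "01": 1, "11": 1})
        assert multiplicative_index(g).estimate == 1.0

    def test_subset_of_three_factor_grid(self, worked_grid):
        m = multiplicative_index(worked_grid, ("low_MD", "high_BMI"))
        # only the two-way product term survives in the ratio
        assert m.estimate == pytest.approx(np.exp(-0.27))

    def test_too_small_subset(self, worked_grid):
        with pytest.raises(DimensionalityError):
            multiplicative_index(worked_grid, ("low_MD",))


class TestClassify:
    def test_superadditive_with_ci(self):
        m = InteractionMeasure(
            MeasureKind.RERI_TOP, ("A", "B", "C"), (), 1.98, se=1.01, ci=(0.00, 3.96)
        )
        label, excludes = classify(m)
        assert label == "super-additive"
        assert excludes is False  # CI touches 0

    def test_additive_point(self):
        m = InteractionMeasure(MeasureKind.TOT_RERI, ("A", "B"), (), 0.0)
        assert classify(m).label == "additive"

    def test_subadditive_ci_includes_zero(self):
        m = InteractionMeasure(
            MeasureKind.CONDITIONAL_RERI,
            ("A", "B"),
            (("C", 0),),
            -0.30,
            se=0.17,
            ci=(-0.64, 0.03),
        )
        label, excludes = classify(m)
        assert label == "sub-additive"
        assert excludes is False

    def test_tolerance_band(self):
        m = InteractionMeasure(MeasureKind.TOT_RERI, ("A", "B"), (), 0.05)
        assert classify(m, tolerance=0.1).label == "additive"
        assert classify(m).label == "super-additive"

    def test_multiplicative_index_rejected(self):
        m = InteractionMeasure(MeasureKind.MULT_INDEX, ("A", "B"), (), 1.5)
        with pytest.raises(MeasureKindError):
            classify(m)


class TestAlgebraicProperties:
    """Seeded spot-checks of the measure identities; the full 1000-grid
    sweep runs in the acceptance suite."""

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_decomposition_identity(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(25):
            g = random_grid(rng, n)
            assert sum(p.estimate for p in decompose(g)) == pytest.approx(
                tot_reri(g).estimate, rel=1e-10, abs=1e-10
            )

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_recursion_over_every_pivot(self, n):
        # RERI_n = RERI_{n-1}(rest | pivot present) * RR(pivot alone)
        #          - RERI_{n-1}(rest | pivot absent)
        rng = np.random.default_rng(200 + n)
        for _ in range(10):
            g = random_grid(rng, n)
            top = reri_top(g).estimate
            for i, pivot in enumerate(g.factor_names):
                rest = tuple(f for f in g.factor_names if f != pivot)
                hi = conditional_reri(g, rest, {pivot: 1}).estimate
                lo = conditional_reri(g, rest, {pivot: 0}).estimate
                assert hi * g.values[1 << i] - lo == pytest.approx(
                    top, rel=1e-10, abs=1e-10
                )

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_additivity_null(self, n):
        rng = np.random.default_rng(300 + n)
        for _ in range(20):
            g = additive_grid(rng.uniform(0.1, 3.0, n))
            assert reri_top(g).estimate == pytest.approx(0.0, abs=1e-10)
            assert tot_reri(g).estimate == pytest.approx(0.0, abs=1e-10)
            for p in decompose(g):
                assert p.estimate == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_multiplicative_implies_additive_direction(self, n):
        # with all single-factor RRs >= 1: index >= 1 => TotRERI >= 0,
        # and TotRERI <= 0 => index <= 1
        rng = np.random.default_rng(400 + n)
        for _ in range(200):
            g = random_grid(rng, n, risk_oriented=True)
            idx = multiplicative_index(g).estimate
            tot = tot_reri(g).estimate
            if idx >= 1.0:
                assert tot >= -1e-12
            if tot <= 0.0:
                assert idx <= 1.0 + 1e-12

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        g = random_grid(rng, 4)
        order = ["X3", "X1", "X4", "X2"]
        h = g.permute(order)
        assert reri_top(h).estimate == pytest.approx(reri_top(g).estimate, rel=1e-12)
        assert tot_reri(h).estimate == pytest.approx(tot_reri(g).estimate, rel=1e-12)
        # a conditional measure follows the relabelling
        a = conditional_reri(g, ("X1", "X2"), {"X3": 1, "X4": 0}).estimate
        b = conditional_reri(h, ("X1", "X2"), {"X3": 1, "X4": 0}).estimate
        assert a == pytest.approx(b, rel=1e-12)
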