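"""Additive (and multiplicative) interaction measures on relative-risk grids.

For two binary risk factors the relative excess risk due to interaction is

    RERI_2 = RR_11 - RR_10 - RR_01 + 1,

positive under super-additivity, zero under exact additivity, negative
under sub-additivity.  With n >= 3 factors this splits into a family of
measures, all of them alternating (inclusion–exclusion) sums of pattern
relative risks:

* ``tot_reri`` — the *total* RERI, contrasting the joint excess risk of all
  n factors with the sum of the n single-factor excess risks:
  RR(all present) - sum_i RR(only i) + (n - 1).
* ``reri_top`` — the n-way interaction net of every lower-order
  interaction: sum over all 2^n patterns of (-1)^(n - k) RR(pattern), where
  k is the number of present factors.
* ``conditional_reri`` — a lower-order RERI for a subset S of factors
  inside a fixed stratum z of the remaining factors; when conditioning
  factors are present, risks are re-referenced by dividing by the stratum
  baseline RR.
* ``decompose`` — TotRERI as the exact sum of the top-order RERI and every
  lower-order conditional RERI taken with the non-involved factors absent.
* ``multiplicative_index`` — RR(joint) / prod RR(single), the departure
  from multiplicativity (1 = exactly multiplicative).

Every RERI-family measure is a ratio of a signed linear combination of
pattern RRs to a single re-referencing RR; :func:`linear_form` exposes that
representation, which downstream code reuses for analytic delta-method
gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

from .exceptions import (
    DimensionalityError,
    MeasureKindError,
    SpecificationError,
)
from .grid import RelativeRiskGrid, mask_to_string


class MeasureKind(str, Enum):
    CONDITIONAL_RERI = "RERI_k_conditional"
    TOT_RERI = "TotRERI"
    RERI_TOP = "RERI_top"
    MULT_INDEX = "MultIndex"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


RERI_KINDS = frozenset(
    {MeasureKind.CONDITIONAL_RERI, MeasureKind.TOT_RERI, MeasureKind.RERI_TOP}
)


@dataclass(frozen=True)
class MeasureSpec:
    """Identifies one interaction measure: its kind, the interacting factor
    subset, and (for conditional measures) the 0/1 assignment of every
    remaining factor."""

    kind: MeasureKind
    subset: tuple[str, ...]
    conditioning: tuple[tuple[str, int], ...] = ()

    @property
    def conditioning_dict(self) -> dict[str, int]:
        return dict(self.conditioning)

    def label(self) -> str:
        """Human-readable name, e.g. ``RERI_2(A,B | C=1)`` or ``TotRERI_3(A,B,C)``."""
        k = len(self.subset)
        inside = ",".join(self.subset)
        if self.kind is MeasureKind.TOT_RERI:
            return f"TotRERI_{k}({inside})"
        if self.kind is MeasureKind.RERI_TOP:
            return f"RERI_{k}({inside})"
        if self.kind is MeasureKind.MULT_INDEX:
            return f"I_{k}({inside})"
        cond = ",".join(f"{f}={v}" for f, v in self.conditioning)
        return f"RERI_{k}({inside} | {cond})" if cond else f"RERI_{k}({inside})"


@dataclass(frozen=True)
class InteractionMeasure:
    """One computed interaction quantity with optional uncertainty."""

    kind: MeasureKind
    subset: tuple[str, ...]
    conditioning: tuple[tuple[str, int], ...]
    estimate: float
    se: Optional[float] = None
    ci: Optional[tuple[float, float]] = None
    level: float = 0.95

    def __post_init__(self):
        if self.kind in RERI_KINDS and len(self.subset) < 2:
            raise SpecificationError(
                f"{self.kind} requires a subset of at least two factors, got {self.subset}"
            )
        overlap = set(self.subset) & {f for f, _ in self.conditioning}
        if overlap:
            raise SpecificationError(
                f"subset and conditioning overlap on {sorted(overlap)}"
            )
        if self.ci is not None:
            lo, hi = self.ci
            if not (lo <= self.estimate <= hi):
                raise SpecificationError(
                    f"estimate {self.estimate} outside its CI ({lo}, {hi})"
                )

    @property
    def spec(self) -> MeasureSpec:
        return MeasureSpec(self.kind, self.subset, self.conditioning)

    def label(self) -> str:
        return self.spec.label()

    def __repr__(self) -> str:
        s = f"{self.label()} = {self.estimate:.4g}"
        if self.se is not None:
            s += f" (se {self.se:.4g})"
        if self.ci is not None:
            s += f" [{self.level:.0%} CI {self.ci[0]:.4g}, {self.ci[1]:.4g}]"
        return s


class LinearForm(NamedTuple):
    """A RERI-family measure written as (sum_p coeff_p * RR_p) / RR_denom.

    ``coeffs`` maps pattern bitmasks to the signed inclusion–exclusion
    coefficients; ``denom_mask`` is the bitmask of the re-referencing
    stratum pattern (0 for unconditional measures, where RR = 1)."""

    coeffs: dict[int, float]
    denom_mask: int


def linear_form(spec: MeasureSpec, factor_names: Sequence[str]) -> LinearForm:
    """Signed-sum representation of a RERI-family measure over pattern masks."""
    if spec.kind not in RERI_KINDS:
        raise MeasureKindError(f"{spec.kind} has no RERI-style linear form")
    n = len(factor_names)
    index = {f: i for i, f in enumerate(factor_names)}
    try:
        sub_bits = [index[f] for f in spec.subset]
    except KeyError as e:
        raise SpecificationError(f"unknown factor {e.args[0]!r}") from None
    if len(set(sub_bits)) != len(sub_bits):
        raise SpecificationError(f"subset {spec.subset} contains duplicates")
    k = len(sub_bits)
    if k < 2:
        raise DimensionalityError(
            f"interaction measures need at least 2 factors, got subset {spec.subset}"
        )

    if spec.kind is MeasureKind.TOT_RERI:
        if spec.conditioning or k != n:
            raise SpecificationError("TotRERI is defined over all factors, unconditioned")
        coeffs: dict[int, float] = {(1 << n) - 1: 1.0, 0: float(n - 1)}
        for i in range(n):
            coeffs[1 << i] = coeffs.get(1 << i, 0.0) - 1.0
        return LinearForm(coeffs, 0)

    if spec.kind is MeasureKind.RERI_TOP:
        if spec.conditioning or k != n:
            raise SpecificationError("the top-order RERI spans all factors, unconditioned")
        coeffs = {m: float((-1) ** (n - bin(m).count("1"))) for m in range(1 << n)}
        return LinearForm(coeffs, 0)

    # conditional RERI over subset S within stratum z
    cond = dict(spec.conditioning)
    rest = [f for f in factor_names if f not in spec.subset]
    if set(cond) != set(rest):
        missing = set(rest) - set(cond)
        extra = set(cond) - set(rest)
        raise SpecificationError(
            "conditioning must assign 0/1 to exactly the factors outside the subset"
            + (f"; missing {sorted(missing)}" if missing else "")
            + (f"; unexpected {sorted(extra)}" if extra else "")
        )
    z_mask = 0
    for f, v in cond.items():
        if v not in (0, 1):
            raise SpecificationError(f"conditioning value for {f!r} must be 0 or 1, got {v}")
        if v:
            z_mask |= 1 << index[f]
    coeffs = {}
    for r in range(k + 1):
        for combo in combinations(sub_bits, r):
            s_mask = 0
            for b in combo:
                s_mask |= 1 << b
            coeffs[s_mask | z_mask] = coeffs.get(s_mask | z_mask, 0.0) + (-1.0) ** (k - r)
    return LinearForm(coeffs, z_mask)


def evaluate_spec(grid: RelativeRiskGrid, spec: MeasureSpec) -> float:
    """Point estimate of any measure spec on a grid."""
    if spec.kind is MeasureKind.MULT_INDEX:
        num = grid.values[grid.subset_mask(spec.subset)]
        den = 1.0
        for f in spec.subset:
            den *= grid.values[1 << grid.factor_index(f)]
        return float(num / den)
    form = linear_form(spec, grid.factor_names)
    num = sum(c * grid.values[m] for m, c in form.coeffs.items())
    return float(num / grid.values[form.denom_mask])


def _measure(grid: RelativeRiskGrid, spec: MeasureSpec) -> InteractionMeasure:
    return InteractionMeasure(
        kind=spec.kind,
        subset=spec.subset,
        conditioning=spec.conditioning,
        estimate=evaluate_spec(grid, spec),
    )


def _require_n(grid: RelativeRiskGrid, minimum: int, what: str) -> None:
    if grid.n < minimum:
        raise DimensionalityError(
            f"{what} requires at least {minimum} factors, grid has {grid.n}"
        )


def reri2(grid: RelativeRiskGrid) -> InteractionMeasure:
    """Two-factor RERI = RR_11 - RR_10 - RR_01 + 1.  Exactly-2-factor grids
    only; for subsets of larger grids use :func:`conditional_reri`, and for
    the joint top-order measure use :func:`reri_top`."""
    if grid.n != 2:
        raise DimensionalityError(
            f"reri2 is defined for exactly 2 factors, grid has {grid.n}; "
            "use conditional_reri or reri_top for larger grids"
        )
    return _measure(grid, MeasureSpec(MeasureKind.RERI_TOP, grid.factor_names))


def tot_reri(grid: RelativeRiskGrid) -> InteractionMeasure:
    """Total RERI: RR(all present) - sum_i RR(only i present) + (n - 1)."""
    _require_n(grid, 2, "tot_reri")
    return _measure(grid, MeasureSpec(MeasureKind.TOT_RERI, grid.factor_names))


def reri_top(grid: RelativeRiskGrid) -> InteractionMeasure:
    """The n-way RERI net of all lower-order interactions: the alternating
    inclusion–exclusion sum of all 2^n pattern RRs."""
    _require_n(grid, 2, "reri_top")
    return _measure(grid, MeasureSpec(MeasureKind.RERI_TOP, grid.factor_names))


def conditional_reri(
    grid: RelativeRiskGrid,
    subset: Sequence[str],
    conditioning: Mapping[str, int],
) -> InteractionMeasure:
    """RERI of ``subset`` within the stratum where the remaining factors are
    fixed at ``conditioning``; RRs are re-referenced to the stratum baseline
    (division by RR of the conditioning pattern), so an all-absent stratum
    recovers the plain formula."""
    spec = MeasureSpec(
        MeasureKind.CONDITIONAL_RERI,
        tuple(subset),
        tuple(sorted(conditioning.items(), key=lambda kv: grid.factor_index(kv[0]))),
    )
    linear_form(spec, grid.factor_names)  # validates subset/conditioning
    return _measure(grid, spec)


def decomposition_specs(factor_names: Sequence[str]) -> list[MeasureSpec]:
    """The measure set whose estimates sum exactly to TotRERI: the top-order
    RERI plus, for every proper subset S with \\|S\\| >= 2, the conditional
    RERI of S with all other factors absent.  Ordered top-order first, then
    by decreasing subset size, then lexicographically by factor position."""
    names = tuple(factor_names)
    n = len(names)
    specs = [MeasureSpec(MeasureKind.RERI_TOP, names)]
    for size in range(n - 1, 1, -1):
        for combo in combinations(range(n), size):
            subset = tuple(names[i] for i in combo)
            cond = tuple((names[i], 0) for i in range(n) if i not in combo)
            specs.append(MeasureSpec(MeasureKind.CONDITIONAL_RERI, subset, cond))
    return specs


def decompose(grid: RelativeRiskGrid) -> list[InteractionMeasure]:
    """Exact additive decomposition of TotRERI.

    Returns the top-order RERI over all n factors followed by the
    conditional RERI of every proper subset (size >= 2) taken with the
    non-involved factors absent.  The estimates sum to ``tot_reri(grid)``
    identically (an inclusion–exclusion cancellation), which is the
    decomposition property the measures are designed around.
    """
    _require_n(grid, 2, "decompose")
    return [_measure(grid, spec) for spec in decomposition_specs(grid.factor_names)]


def multiplicative_index(
    grid: RelativeRiskGrid, subset: Optional[Sequence[str]] = None
) -> InteractionMeasure:
    """Departure from multiplicativity: RR(all of S present, others absent)
    divided by the product of the single-factor RRs of S.  The printed
    two-factor index generalizes naturally to larger subsets."""
    names = tuple(subset) if subset is not None else grid.factor_names
    if len(names) < 2:
        raise DimensionalityError(
            f"multiplicative index needs at least 2 factors, got {names}"
        )
    spec = MeasureSpec(MeasureKind.MULT_INDEX, names)
    return _measure(grid, spec)


class Classification(NamedTuple):
    label: str  # "super-additive" | "additive" | "sub-additive"
    ci_excludes_zero: Optional[bool]  # None when no CI is attached


def classify(measure: InteractionMeasure, tolerance: float = 0.0) -> Classification:
    """Sign classification of a RERI measure.

    ``super-additive`` when the estimate exceeds ``tolerance``,
    ``sub-additive`` below ``-tolerance``, ``additive`` otherwise.  The
    default tolerance of 0 classifies strictly by sign.  When a confidence
    interval is attached, the second field reports whether it excludes 0.
    Multiplicative indices compare to 1, not 0, and are rejected here.
    """
    if measure.kind not in RERI_KINDS:
        raise MeasureKindError(
            f"classify applies to RERI measures, not {measure.kind}; "
            "a multiplicative index is compared to 1 instead"
        )
    if tolerance < 0:
        raise SpecificationError(f"tolerance must be >= 0, got {tolerance}")
    if measure.estimate > tolerance:
        label = "super-additive"
    elif measure.estimate < -tolerance:
        label = "sub-additive"
    else:
        label = "additive"
    excludes = None
    if measure.ci is not None:
        lo, hi = measure.ci
        excludes = lo > 0 or hi < 0
    return Classification(label, excludes)


def all_conditional_specs(
    factor_names: Sequence[str], max_strata_factors: int = 6
) -> list[MeasureSpec]:
    """Every conditional RERI over every proper subset and every stratum of
    the remaining factors — the full worked-report measure set (for three
    factors: six conditional two-way RERIs).  Capped to avoid combinatorial
    blow-up for very wide grids."""
    names = tuple(factor_names)
    n = len(names)
    if n > max_strata_factors:
        return [s for s in decomposition_specs(names) if s.kind is MeasureKind.CONDITIONAL_RERI]
    specs = []
    for size in range(2, n):
        for combo in combinations(range(n), size):
            subset = tuple(names[i] for i in combo)
            rest = [i for i in range(n) if i not in combo]
            for stratum in range(1 << len(rest)):
                cond = tuple(
                    (names[i], (stratum >> j) & 1) for j, i in enumerate(rest)
                )
                specs.append(MeasureSpec(MeasureKind.CONDITIONAL_RERI, subset, cond))
    return specs
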