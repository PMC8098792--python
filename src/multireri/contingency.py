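"""Model-free estimation of a relative-risk grid from a 2^n contingency table.

For cohort counts, each pattern's risk is cases/denominator (or a rate when
the denominator is person-time) and RRs are referenced to the all-absent
cell.  Per-pattern log-RR variances use the standard large-sample forms

    subjects:     1/a_p - 1/N_p + 1/a_0 - 1/N_0
    person-time:  1/a_p + 1/a_0

Cells are assumed independent, so the only covariance between two log-RRs
is the shared reference-cell contribution.  To reuse the delta-method
machinery, the estimated log-RRs are converted into a saturated
:class:`~multireri.model.CoefficientSet` by Möbius inversion (the
coefficient of a factor subset T is the alternating sum of log-RRs of T's
sub-patterns), and the per-cell log-risk variances are pushed through that
linear map exactly — including the common reference-cell term — so
downstream delta-method SEs for every interaction measure are consistent
with the stated variance formulas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    InfiniteVarianceWarning,
    InvalidTableError,
    RareDiseaseWarning,
)
from .grid import (
    RelativeRiskGrid,
    canonical_masks,
    mask_to_string,
    pattern_to_mask,
)
from .model import CoefficientSet

logger = logging.getLogger(__name__)


@dataclass
class CohortTable:
    """Aggregated cohort data: one row per exposure pattern.

    ``cases`` and ``denominators`` are arrays of length 2^n indexed by
    pattern bitmask; the denominator is a subject count
    (``denominator_kind='subjects'``) or accumulated person-time
    (``'person_time'``).
    """

    factor_names: tuple[str, ...]
    cases: np.ndarray
    denominators: np.ndarray
    denominator_kind: str = "subjects"

    def __post_init__(self):
        self.factor_names = tuple(self.factor_names)
        n = len(self.factor_names)
        self.cases = np.asarray(self.cases, dtype=float)
        self.denominators = np.asarray(self.denominators, dtype=float)
        if self.denominator_kind not in ("subjects", "person_time"):
            raise InvalidTableError(
                f"denominator_kind must be 'subjects' or 'person_time', "
                f"got {self.denominator_kind!r}"
            )
        if self.cases.shape != (1 << n,) or self.denominators.shape != (1 << n,):
            raise InvalidTableError(f"table needs exactly {1 << n} rows (one per pattern)")
        if np.any(self.cases < 0):
            raise InvalidTableError("case counts must be >= 0")
        if np.any(self.denominators <= 0):
            bad = int(np.argmax(self.denominators <= 0))
            raise InvalidTableError(
                f"pattern '{mask_to_string(bad, n)}' has non-positive denominator"
            )
        if self.denominator_kind == "subjects" and np.any(self.cases > self.denominators):
            raise InvalidTableError("cases exceed subject denominators")
        if self.cases[0] < 1:
            raise InvalidTableError(
                "the all-absent reference cell has no cases; relative risks are undefined"
            )

    @property
    def n(self) -> int:
        return len(self.factor_names)

    @classmethod
    def from_patterns(
        cls,
        factor_names: Sequence[str],
        cases: Mapping[str, float],
        denominators: Mapping[str, float],
        denominator_kind: str = "subjects",
    ) -> "CohortTable":
        n = len(factor_names)
        a = np.zeros(1 << n)
        d = np.zeros(1 << n)
        seen = set()
        for pattern, c in cases.items():
            m = pattern_to_mask(pattern, n)
            a[m] = c
            seen.add(m)
        if seen != set(range(1 << n)):
            missing = sorted(set(range(1 << n)) - seen)
            raise InvalidTableError(
                "missing pattern(s): " + ", ".join(mask_to_string(m, n) for m in missing[:8])
            )
        for pattern, v in denominators.items():
            d[pattern_to_mask(pattern, n)] = v
        return cls(tuple(factor_names), a, d, denominator_kind)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        factor_names: Optional[Sequence[str]] = None,
        denominator_kind: str = "subjects",
    ) -> "CohortTable":
        """Read a long table with columns ``pattern``, ``cases``,
        ``denominator`` — or wide per-factor 0/1 indicator columns plus
        ``cases`` and ``denominator``."""
        cols = set(df.columns)
        if {"pattern", "cases", "denominator"} <= cols:
            patterns = df["pattern"].astype(str)
            n = len(patterns.iloc[0])
            if factor_names is None:
                factor_names = [f"X{i + 1}" for i in range(n)]
        else:
            if factor_names is None:
                factor_names = [c for c in df.columns if c not in ("cases", "denominator")]
            if not {"cases", "denominator"} <= cols:
                raise InvalidTableError(
                    f"table needs 'cases' and 'denominator' columns (got {sorted(cols)})"
                )
            patterns = df[list(factor_names)].astype(int).astype(str).agg("".join, axis=1)
        cases = dict(zip(patterns, df["cases"].astype(float)))
        denoms = dict(zip(patterns, df["denominator"].astype(float)))
        if len(cases) != len(df):
            raise InvalidTableError("duplicate pattern rows in table")
        return cls.from_patterns(factor_names, cases, denoms, denominator_kind)

    @classmethod
    def read(cls, path, sep="\t", **kwargs) -> "CohortTable":
        df = pd.read_csv(path, sep=sep, dtype={"pattern": str})
        return cls.from_frame(df, **kwargs)


def _estimate_cells(
    table: CohortTable, continuity_correction: bool, effect_measure: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell effect estimates and log-scale variances.

    Returns ``(risk, var_cell)`` where ``risk`` is the cell risk, rate, or
    odds and ``var_cell`` the variance of its log.  Warns on zero-case
    cells; with ``continuity_correction`` a +0.5 is added to every cell
    whenever any cell would otherwise be degenerate.
    """
    if effect_measure not in ("risk", "odds"):
        raise InvalidTableError(
            f"effect_measure must be 'risk' or 'odds', got {effect_measure!r}"
        )
    n = table.n
    a = table.cases.copy()
    d = table.denominators.copy()
    if effect_measure == "odds":
        if table.denominator_kind != "subjects":
            raise InvalidTableError("odds ratios need subject-count denominators")
        warnings.warn(
            "odds ratios approximate relative risks only when the outcome is rare",
            RareDiseaseWarning,
            stacklevel=3,
        )
    zero_cells = np.flatnonzero(a == 0)
    degenerate = len(zero_cells) > 0 or (effect_measure == "odds" and np.any(a == d))
    if len(zero_cells) > 0:
        warnings.warn(
            "zero cases in pattern(s) "
            + ", ".join(mask_to_string(int(m), n) for m in zero_cells)
            + ": log-RR variance is infinite"
            + (
                "; applying +0.5 continuity correction to all cells"
                if continuity_correction
                else " (pass continuity_correction=True to add 0.5 to all cells)"
            ),
            InfiniteVarianceWarning,
            stacklevel=3,
        )
    if degenerate and continuity_correction:
        logger.info("continuity correction: +0.5 added to every cell")
        a = a + 0.5
        d = d + (1.0 if effect_measure == "odds" else
                 (1.0 if table.denominator_kind == "subjects" else 0.5))
    with np.errstate(divide="ignore"):
        if effect_measure == "odds":
            risk = a / (d - a)
            var_cell = 1.0 / a + 1.0 / (d - a)
        elif table.denominator_kind == "subjects":
            risk = a / d
            var_cell = 1.0 / a - 1.0 / d
        else:
            risk = a / d
            var_cell = 1.0 / a
    return risk, var_cell


def rr_grid_from_counts(
    table: CohortTable,
    continuity_correction: bool = False,
    effect_measure: str = "risk",
) -> tuple[RelativeRiskGrid, dict[str, float]]:
    """Estimate the RR grid and per-pattern log-RR variances from counts.

    Returns ``(grid, var_log_rr)`` where ``var_log_rr`` maps each
    non-reference pattern string to the variance of its log relative risk
    (cell variance plus the shared reference-cell variance).
    ``effect_measure='odds'`` switches to odds ratios for case–control
    input, with a rare-disease warning.
    """
    risk, var_cell = _estimate_cells(table, continuity_correction, effect_measure)
    if np.any(risk == 0):
        bad = int(np.argmax(risk == 0))
        raise InvalidTableError(
            f"pattern '{mask_to_string(bad, table.n)}' has zero estimated risk; "
            "use continuity_correction=True"
        )
    grid = RelativeRiskGrid(table.factor_names, risk / risk[0])
    var_log_rr = {
        mask_to_string(m, table.n): float(var_cell[m] + var_cell[0])
        for m in canonical_masks(table.n)
        if m != 0
    }
    return grid, var_log_rr


def coefficient_set_from_counts(
    table: CohortTable,
    continuity_correction: bool = False,
    effect_measure: str = "risk",
) -> CoefficientSet:
    """Saturated coefficient set (with full covariance) from a count table.

    The coefficient of factor subset T is the Möbius inversion of the
    estimated log-RRs — exactly what a saturated log-linear risk model
    would estimate — and the covariance propagates the independent
    per-cell log-risk variances through that linear map, so delta-method
    SEs downstream account for the shared reference cell.
    """
    risk, var_cell = _estimate_cells(table, continuity_correction, effect_measure)
    if not np.all(np.isfinite(var_cell)) or np.any(risk == 0):
        raise InvalidTableError(
            "infinite log-RR variance (zero-case cell); "
            "use continuity_correction=True to proceed"
        )
    n = table.n
    log_rr = np.log(risk / risk[0])
    # Möbius (inverse zeta) transform: beta_T = alternating sum over s <= T
    beta = log_rr.copy()
    for i in range(n):
        bit = 1 << i
        for m in range(1 << n):
            if m & bit:
                beta[m] -= beta[m ^ bit]
    term_masks = [m for m in canonical_masks(n) if m]
    # Sensitivity of each beta_T to each cell's log-risk; cells independent.
    t = len(term_masks)
    A = np.zeros((t, 1 << n))
    for j, tm in enumerate(term_masks):
        bits = [i for i in range(n) if (tm >> i) & 1]
        for r in range(len(bits) + 1):
            for combo in combinations(bits, r):
                s = 0
                for b in combo:
                    s |= 1 << b
                A[j, s] += (-1.0) ** (len(bits) - r)
    vcov = (A * var_cell) @ A.T
    return CoefficientSet(
        table.factor_names, {m: float(beta[m]) for m in term_masks}, vcov=vcov
    )
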