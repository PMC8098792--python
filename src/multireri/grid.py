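"""Relative-risk grids over the 2^n exposure patterns of n binary factors.

The central container is :class:`RelativeRiskGrid`: a complete mapping from
every combination of presence/absence of ``n`` binary risk factors to the
relative risk (or rate/hazard/odds ratio) of the outcome for that
combination, referenced to the all-absent pattern (whose RR is 1 by
definition).  Patterns are tuples of 0/1 indicators aligned with the grid's
factor order; internally each pattern is a bitmask with bit ``i`` set when
factor ``i`` is present, which keeps the inclusion–exclusion sums used by
the interaction measures cheap and auditable.

Grids are exact, dense enumerations: the factor count is capped at 16 so
that 2^n stays small and every identity can be checked brute force.
"""

from __future__ import annotations

import json
import math
from collections.abc import Iterable, Mapping, Sequence
from typing import Union

import numpy as np

from .exceptions import (
    IncompleteGridError,
    InvalidRiskError,
    NamingError,
    PatternLookupError,
)

MAX_FACTORS = 16

PatternLike = Union[str, Sequence[int]]


def pattern_to_mask(pattern: PatternLike, n: int) -> int:
    """Convert a pattern ('101' or (1, 0, 1)) to its bitmask for an n-factor grid.

    Bit ``i`` of the mask corresponds to factor ``i`` in the grid's factor
    order, i.e. to position ``i`` of the pattern string.
    """
    if isinstance(pattern, str):
        states: Sequence[int] = [int(c) for c in pattern] if pattern.strip("01") == "" else None  # type: ignore[assignment]
        if states is None:
            raise PatternLookupError(f"pattern string {pattern!r} must consist of 0s and 1s")
    else:
        states = list(pattern)
    if len(states) != n:
        raise PatternLookupError(
            f"pattern {pattern!r} has length {len(states)}, expected {n}"
        )
    mask = 0
    for i, s in enumerate(states):
        if s not in (0, 1):
            raise PatternLookupError(f"pattern {pattern!r} contains non-binary entry {s!r}")
        mask |= int(s) << i
    return mask


def mask_to_pattern(mask: int, n: int) -> tuple[int, ...]:
    return tuple((mask >> i) & 1 for i in range(n))


def mask_to_string(mask: int, n: int) -> str:
    return "".join(str((mask >> i) & 1) for i in range(n))


def canonical_masks(n: int) -> list[int]:
    """All 2^n pattern bitmasks ordered by number of present factors, ties
    broken lexicographically by the indices of the present factors.  This
    is the enumeration order used for serialization and reporting (main
    effects in factor order, then two-way terms, ...); it makes
    inclusion–exclusion sums easy to audit by eye."""
    return sorted(
        range(1 << n),
        key=lambda m: (bin(m).count("1"), [i for i in range(n) if (m >> i) & 1]),
    )


class RelativeRiskGrid:
    """Complete map from exposure patterns to relative risks.

    Parameters
    ----------
    factor_names
        Distinct labels for the n binary factors, in pattern order.
    rr
        Array of length 2^n, indexed by pattern bitmask (bit i = factor i
        present).  ``rr[0]`` must be exactly 1 and every entry positive.
    """

    __slots__ = ("factor_names", "_rr")

    def __init__(self, factor_names: Sequence[str], rr: np.ndarray):
        names = tuple(str(f) for f in factor_names)
        if len(set(names)) != len(names):
            raise NamingError(f"factor names must be distinct, got {names}")
        n = len(names)
        if not 1 <= n <= MAX_FACTORS:
            raise NamingError(f"factor count must be in [1, {MAX_FACTORS}], got {n}")
        rr = np.asarray(rr, dtype=float)
        if rr.shape != (1 << n,):
            raise IncompleteGridError(
                f"expected {1 << n} relative risks for {n} factors, got shape {rr.shape}"
            )
        if not np.all(np.isfinite(rr)) or np.any(rr <= 0):
            bad = int(np.argmin(np.where(np.isfinite(rr), rr, -np.inf)))
            raise InvalidRiskError(
                f"relative risks must be finite and > 0; "
                f"pattern '{mask_to_string(bad, n)}' has RR = {rr[bad]}"
            )
        if rr[0] != 1.0:
            raise InvalidRiskError(
                f"the all-absent reference pattern must have RR = 1, got {rr[0]}"
            )
        self.factor_names = names
        self._rr = rr
        self._rr.flags.writeable = False

    # -- basic queries -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.factor_names)

    @property
    def values(self) -> np.ndarray:
        """Read-only RR array indexed by pattern bitmask."""
        return self._rr

    def mask(self, pattern: PatternLike) -> int:
        return pattern_to_mask(pattern, self.n)

    def rr(self, pattern: PatternLike) -> float:
        """Relative risk of one pattern (string '101' or 0/1 sequence)."""
        return float(self._rr[self.mask(pattern)])

    def rr_by_mask(self, mask: int) -> float:
        if not 0 <= mask < (1 << self.n):
            raise PatternLookupError(f"mask {mask} out of range for {self.n} factors")
        return float(self._rr[mask])

    def patterns(self) -> list[tuple[int, ...]]:
        """All patterns in canonical order (by count of present factors)."""
        return [mask_to_pattern(m, self.n) for m in canonical_masks(self.n)]

    def factor_index(self, name: str) -> int:
        try:
            return self.factor_names.index(name)
        except ValueError:
            raise NamingError(
                f"unknown factor {name!r}; grid factors are {self.factor_names}"
            ) from None

    def subset_mask(self, names: Iterable[str]) -> int:
        mask = 0
        for name in names:
            mask |= 1 << self.factor_index(name)
        return mask

    def rename(self, mapping: Mapping[str, str]) -> "RelativeRiskGrid":
        new_names = [mapping.get(f, f) for f in self.factor_names]
        return RelativeRiskGrid(new_names, self._rr.copy())

    def permute(self, order: Sequence[str]) -> "RelativeRiskGrid":
        """Reorder factors; RRs follow the relabelled patterns."""
        idx = [self.factor_index(f) for f in order]
        if sorted(idx) != list(range(self.n)):
            raise NamingError(f"order {order!r} is not a permutation of {self.factor_names}")
        new_rr = np.empty_like(np.asarray(self._rr))
        for m in range(1 << self.n):
            old = 0
            for new_bit, old_bit in enumerate(idx):
                if (m >> new_bit) & 1:
                    old |= 1 << old_bit
            new_rr[m] = self._rr[old]
        return RelativeRiskGrid(order, new_rr)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "factors": list(self.factor_names),
            "rr": {
                mask_to_string(m, self.n): float(self._rr[m])
                for m in canonical_masks(self.n)
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RelativeRiskGrid":
        return make_rr_grid(d["factors"], d["rr"])

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "RelativeRiskGrid":
        try:
            d = json.loads(path_or_text)
        except (json.JSONDecodeError, TypeError):
            with open(path_or_text) as fh:
                d = json.load(fh)
        return cls.from_dict(d)

    def to_tsv(self, path=None, sep: str = "\t") -> str:
        """Two-column text: header row of factor names, then pattern / RR rows."""
        lines = [sep.join(self.factor_names)]
        lines += [
            f"{mask_to_string(m, self.n)}{sep}{self._rr[m]:.12g}"
            for m in canonical_masks(self.n)
        ]
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_tsv(cls, path, sep: str = "\t") -> "RelativeRiskGrid":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        factors = lines[0].split(sep)
        rr = {}
        for ln in lines[1:]:
            pattern, value = ln.split(sep)[:2]
            rr[pattern] = float(value)
        return make_rr_grid(factors, rr)

    def __repr__(self) -> str:
        return f"RelativeRiskGrid(factors={self.factor_names}, n_patterns={1 << self.n})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RelativeRiskGrid)
            and self.factor_names == other.factor_names
            and np.array_equal(self._rr, other._rr)
        )

    def allclose(self, other: "RelativeRiskGrid", rtol=1e-12, atol=0.0) -> bool:
        return self.factor_names == other.factor_names and np.allclose(
            self._rr, other._rr, rtol=rtol, atol=atol
        )


def make_rr_grid(
    factor_names: Sequence[str],
    rr_by_pattern: Mapping[PatternLike, float],
) -> RelativeRiskGrid:
    """Build a validated grid from a pattern -> RR mapping.

    The all-absent reference pattern may be omitted, in which case RR = 1 is
    implied; if supplied it must equal 1 exactly.  Raises
    :class:`IncompleteGridError` when any other pattern is missing,
    :class:`InvalidRiskError` for non-positive risks, and
    :class:`NamingError` for duplicate factor names.
    """
    names = tuple(str(f) for f in factor_names)
    if len(set(names)) != len(names):
        raise NamingError(f"factor names must be distinct, got {names}")
    n = len(names)
    if not 1 <= n <= MAX_FACTORS:
        raise NamingError(f"factor count must be in [1, {MAX_FACTORS}], got {n}")
    rr = np.full(1 << n, np.nan)
    for pattern, value in rr_by_pattern.items():
        m = pattern_to_mask(pattern, n)
        if not math.isfinite(float(value)) or float(value) <= 0:
            raise InvalidRiskError(
                f"relative risks must be finite and > 0; "
                f"pattern '{mask_to_string(m, n)}' has RR = {value}"
            )
        rr[m] = float(value)
    if np.isnan(rr[0]):
        rr[0] = 1.0
    missing = [mask_to_string(m, n) for m in range(1 << n) if np.isnan(rr[m])]
    if missing:
        raise IncompleteGridError(
            f"grid for {n} factors is missing {len(missing)} pattern(s): "
            + ", ".join(missing[:8])
            + ("..." if len(missing) > 8 else "")
        )
    return RelativeRiskGrid(names, rr)


def excess_rr(grid: RelativeRiskGrid, pattern: PatternLike) -> float:
    """Excess relative risk ERR = RR - 1 for one exposure pattern."""
    return grid.rr(pattern) - 1.0
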