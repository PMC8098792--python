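"""Detection and recoding of protective factors.

Additive-interaction measures are only interpretable when every factor is
a *risk* factor: a protective exposure (single-factor RR < 1) makes the
additivity benchmark nonsensical — two factors each cutting risk by 75%
would, under exact additivity of excess risks, imply a negative joint RR.
The remedy is to recode each protective factor to its complement (the
risk of *not* having the exposure) and re-reference the grid.

Flipping factor i maps every pattern to the same pattern with bit i
inverted; the new reference pattern is the one that is all-absent after
flipping, and every RR is divided by that pattern's old RR so the new
grid is again referenced to 1.
"""

from __future__ import annotations

import warnings
from typing import Iterable, NamedTuple

import numpy as np

from .exceptions import MixedOrientationWarning
from .grid import RelativeRiskGrid


class ProtectiveFactor(NamedTuple):
    name: str
    single_factor_rr: float


NOT_PREFIX = "not_"


def check_risk_orientation(grid: RelativeRiskGrid) -> list[ProtectiveFactor]:
    """Factors whose single-factor RR (all others absent) is below 1.

    An empty list means every factor is risk-oriented and additive
    interaction measures are interpretable as-is.
    """
    flagged = []
    for i, name in enumerate(grid.factor_names):
        rr = float(grid.values[1 << i])
        if rr < 1.0:
            flagged.append(ProtectiveFactor(name, rr))
    return flagged


def _flip_name(name: str) -> str:
    # strip-or-prepend keeps double flips an exact involution on names
    return name[len(NOT_PREFIX):] if name.startswith(NOT_PREFIX) else NOT_PREFIX + name


def reorient(
    grid: RelativeRiskGrid,
    factors_to_flip: Iterable[str],
    rename: bool = True,
) -> RelativeRiskGrid:
    """Recode the given factors to their complements and re-reference.

    Each flipped factor's presence/absence is inverted in every pattern,
    and all RRs are divided by the old RR of the new reference pattern so
    that the returned grid again has RR(all-absent) = 1.  With ``rename``
    (default) flipped factor names gain or lose a ``not_`` prefix to keep
    their meaning explicit.  Flipping the same set twice restores the
    original grid exactly.

    Emits :class:`MixedOrientationWarning` when some single-factor RR is
    still below 1 after flipping (mixed orientation can be unavoidable
    under qualitative interaction; the choice of what to flip next is left
    to the user).
    """
    flip_set = set(factors_to_flip)
    unknown = flip_set - set(grid.factor_names)
    if unknown:
        grid.factor_index(sorted(unknown)[0])  # raises NamingError
    flip_mask = grid.subset_mask(flip_set)
    if flip_mask == 0:
        return grid
    old = grid.values
    new_rr = np.empty_like(np.asarray(old))
    for m in range(1 << grid.n):
        new_rr[m] = old[m ^ flip_mask] / old[flip_mask]
    names = [
        _flip_name(f) if f in flip_set and rename else f for f in grid.factor_names
    ]
    out = RelativeRiskGrid(names, new_rr)
    still = check_risk_orientation(out)
    if still:
        warnings.warn(
            "after reorientation some factors remain protective: "
            + ", ".join(f"{p.name} (RR={p.single_factor_rr:.3g})" for p in still)
            + "; mixed orientation may be unavoidable (qualitative interaction)",
            MixedOrientationWarning,
            stacklevel=2,
        )
    return out


def reorientation_map(factors_to_flip: Iterable[str]) -> dict[str, str]:
    """Old-name -> new-name mapping for a set of flips (for logging)."""
    return {f: _flip_name(f) for f in factors_to_flip}
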