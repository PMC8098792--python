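"""Report rendering: the two-block layout of the worked example's table.

Block one lists the model terms (log-scale coefficient, SE, ratio with a
log-scale Wald CI); block two lists every interaction measure (all
conditional lower-order RERIs stratum by stratum, the top-order RERI, and
TotRERI) with delta-method SEs and symmetric Wald CIs.  A provenance block
records options and any warnings (reorientation, continuity correction,
dropped replicates) so that the machine-readable report is self-describing.
Output is deterministic: no timestamps unless explicitly requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .exceptions import ProtectiveFactorError
from .measures import (
    MeasureKind,
    MeasureSpec,
    all_conditional_specs,
    classify,
    evaluate_spec,
)
from .model import (
    CoefficientSet,
    FittedModel,
    delta_ci,
    rr_grid_from_coefficients,
    term_ratio_ci,
)
from .recode import check_risk_orientation


def report_measure_specs(factor_names: Sequence[str]) -> list[MeasureSpec]:
    """Measure ordering of the worked table: conditional RERIs (absent
    strata before present strata), then the top-order RERI, then TotRERI."""
    names = tuple(factor_names)
    conditional = sorted(
        all_conditional_specs(names),
        key=lambda s: (
            len(s.subset),
            sum(v for _, v in s.conditioning),
            tuple(names.index(f) for f in s.subset),
            tuple(v for _, v in s.conditioning),
        ),
    )
    return [
        *conditional,
        MeasureSpec(MeasureKind.RERI_TOP, names),
        MeasureSpec(MeasureKind.TOT_RERI, names),
    ]


@dataclass
class ReportBundle:
    """A rendered analysis report: machine-readable dict plus plain text."""

    data: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(self.data, indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        terms = pd.DataFrame(self.data["model_terms"])
        measures = pd.DataFrame(self.data["interaction_measures"])
        ratio_label = self.data["provenance"].get("ratio_label", "RR")
        lines = ["Model terms (log scale) and ratio estimates", "-" * 44]
        lines.append(
            terms.to_string(
                index=False, float_format=lambda v: f"{v:.3f}", na_rep="NA"
            )
        )
        lines += ["", f"Additive interaction measures ({ratio_label}-based)", "-" * 44]
        lines.append(
            measures.drop(columns=["kind", "subset", "conditioning"]).to_string(
                index=False, float_format=lambda v: f"{v:.3f}", na_rep="NA"
            )
        )
        notes = self.data["provenance"].get("warnings", [])
        if notes:
            lines += ["", "Notes:"] + [f"  - {w}" for w in notes]
        return "\n".join(lines) + "\n"


def build_report(
    source: Union[CoefficientSet, FittedModel],
    level: float = 0.95,
    *,
    allow_protective: bool = False,
    ratio_label: Optional[str] = None,
    extra_warnings: Sequence[str] = (),
) -> ReportBundle:
    """Assemble the full two-block report from a coefficient set or fit.

    Grids containing protective factors (single-factor RR < 1) are refused
    unless ``allow_protective`` is set, because additive-interaction
    measures on protectively-oriented factors are not interpretable;
    reorient first (``multireri.recode``) or override explicitly.
    """
    warnings_list = list(extra_warnings)
    if isinstance(source, FittedModel):
        coefset = source.coefficients
        family = source.family
        meta = {
            "family": family,
            "n_observations": source.nobs,
            "n_events": source.n_events,
            "covariates": list(source.covariate_estimates.index),
        }
        if ratio_label is None:
            ratio_label = "HR" if family == "proportional_hazards" else "OR"
    else:
        coefset = source
        meta = {}
        if ratio_label is None:
            ratio_label = "RR"

    grid = rr_grid_from_coefficients(coefset)
    protective = check_risk_orientation(grid)
    if protective:
        detail = ", ".join(f"{p.name} ({ratio_label}={p.single_factor_rr:.3g})" for p in protective)
        if not allow_protective:
            raise ProtectiveFactorError(
                f"protective factor(s) detected: {detail}; recode them to their "
                "risk-conferring complements (multireri.recode.reorient) or "
                "pass an explicit override"
            )
        warnings_list.append(
            f"protective factor(s) retained by override: {detail}; "
            "additive-interaction measures may not be interpretable"
        )

    have_vcov = coefset.vcov is not None
    if not have_vcov:
        warnings_list.append(
            "no covariance matrix supplied: point estimates only, SE/CI unavailable"
        )

    term_rows = []
    for t in coefset.term_names:
        r = term_ratio_ci(coefset, t, level=level)
        term_rows.append(
            {
                "term": t,
                "b": r.coefficient,
                "se": r.se,
                ratio_label: r.ratio,
                "ci_lower": r.ci[0] if r.ci else None,
                "ci_upper": r.ci[1] if r.ci else None,
            }
        )

    measure_rows = []
    for spec in report_measure_specs(coefset.factor_names):
        if have_vcov:
            m = delta_ci(coefset, spec, level=level)
            cls = classify(m)
            measure_rows.append(
                {
                    "measure": spec.label(),
                    "estimate": m.estimate,
                    "se": m.se,
                    "ci_lower": m.ci[0],
                    "ci_upper": m.ci[1],
                    "classification": cls.label,
                    "ci_excludes_zero": cls.ci_excludes_zero,
                    "kind": spec.kind.value,
                    "subset": list(spec.subset),
                    "conditioning": dict(spec.conditioning),
                }
            )
        else:
            est = evaluate_spec(grid, spec)
            measure_rows.append(
                {
                    "measure": spec.label(),
                    "estimate": est,
                    "se": None,
                    "ci_lower": None,
                    "ci_upper": None,
                    "classification": (
                        "super-additive" if est > 0 else "sub-additive" if est < 0 else "additive"
                    ),
                    "ci_excludes_zero": None,
                    "kind": spec.kind.value,
                    "subset": list(spec.subset),
                    "conditioning": dict(spec.conditioning),
                }
            )

    data = {
        "model_terms": term_rows,
        "interaction_measures": measure_rows,
        "grid": grid.to_dict(),
        "provenance": {
            "package": "multireri",
            "version": __version__,
            "level": level,
            "ratio_label": ratio_label,
            "warnings": warnings_list,
            **meta,
        },
    }
    return ReportBundle(data)
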