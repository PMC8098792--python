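"""Built-in worked example.

A published cohort analysis of all-cause mortality in adult women studied
the joint effect of three binary risk factors — low adherence to a
Mediterranean-type diet, obesity (BMI >= 30), and current smoking — with
a Cox model containing all three main effects, the three two-way product
terms, and the three-way product term (age- and education-adjusted).
The reported log-hazard coefficients and their standard errors are
reproduced here as a ready-made :class:`~multireri.model.CoefficientSet`;
they are the standard worked input for the interaction measures in this
package.

Only coefficient SEs were published, not their covariances, so the
returned set carries a diagonal covariance matrix by default: single-term
hazard-ratio CIs computed from it match the published ones, but
interaction-measure SEs require the full covariance and are therefore not
reproducible from the published table alone (pass ``vcov=None`` to make
that explicit).
"""

from __future__ import annotations

import numpy as np

from .model import CoefficientSet

FACTORS = ("low_MD", "high_BMI", "smoker")

COEFFICIENTS = {
    "low_MD": 0.36,
    "high_BMI": 0.29,
    "smoker": 0.41,
    "low_MD*high_BMI": -0.27,
    "low_MD*smoker": -0.23,
    "high_BMI*smoker": -0.24,
    "low_MD*high_BMI*smoker": 0.92,
}

STANDARD_ERRORS = {
    "low_MD": 0.09,
    "high_BMI": 0.08,
    "smoker": 0.18,
    "low_MD*high_BMI": 0.12,
    "low_MD*smoker": 0.30,
    "high_BMI*smoker": 0.29,
    "low_MD*high_BMI*smoker": 0.45,
}


def mortality_example(with_diagonal_vcov: bool = True) -> CoefficientSet:
    """The worked-example coefficient set (diet / obesity / smoking on
    mortality).  With ``with_diagonal_vcov`` the published SEs populate a
    diagonal covariance; term-wise ratio CIs are then exact, but
    off-diagonal covariances (not published) are zero."""
    vcov = None
    if with_diagonal_vcov:
        base = CoefficientSet.from_terms(COEFFICIENTS, factor_names=FACTORS)
        vcov = np.diag([STANDARD_ERRORS[t] ** 2 for t in base.term_names])
    return CoefficientSet.from_terms(COEFFICIENTS, vcov=vcov, factor_names=FACTORS)
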