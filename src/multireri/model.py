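"""Bridge from regression models to relative-risk grids with delta-method CIs.

A saturated exposure parameterization — one log-scale coefficient for every
non-empty subset of the n binary factors (n main effects, all product
terms up to the n-way product) — determines the full 2^n relative-risk
grid:  log RR(pattern) is the sum of the coefficients of every subset of
the pattern's present factors.  This module

* holds such coefficient vectors (with their covariance matrix) in
  :class:`CoefficientSet`,
* exponentiates them into a :class:`~multireri.grid.RelativeRiskGrid`,
* fits them from individual-level cohort data by logistic regression or
  Cox proportional hazards (always with every product term — dropping
  terms makes the interaction measures incomputable),
* and propagates coefficient uncertainty to every interaction measure by
  the delta method, with analytic gradients.

Because each RERI-family measure is a ratio of a signed sum of pattern RRs
to a single re-referencing RR (see :mod:`multireri.measures`), and each RR
is the exponential of a subset sum of coefficients, the gradients have a
closed form; a finite-difference fallback exists for verification.

Confidence intervals are Wald intervals: symmetric on the RERI scale, and
log-scale (hence asymmetric) for ratio estimands (single RRs/HRs and the
multiplicative index).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    FitError,
    IncompleteModelError,
    MissingVarianceError,
    NamingError,
    NumericalVarianceError,
    SpecificationError,
    UnidentifiableCellError,
)
from .grid import RelativeRiskGrid, canonical_masks, mask_to_string
from .measures import (
    InteractionMeasure,
    LinearForm,
    MeasureKind,
    MeasureSpec,
    RERI_KINDS,
    evaluate_spec,
    linear_form,
)

TERM_SEP = "*"


def term_name(mask: int, factor_names: Sequence[str]) -> str:
    return TERM_SEP.join(f for i, f in enumerate(factor_names) if (mask >> i) & 1)


class CoefficientSet:
    """Log-scale coefficients for all 2^n - 1 exposure terms, plus optional
    covariance.

    Terms are indexed by the subset of factors they multiply; the canonical
    term order (main effects first, then two-way products, and so on, ties
    lexicographic) is used for the covariance matrix and all serialization.
    """

    __slots__ = ("factor_names", "beta", "vcov", "term_masks")

    def __init__(
        self,
        factor_names: Sequence[str],
        beta_by_mask: Mapping[int, float],
        vcov: Optional[np.ndarray] = None,
    ):
        names = tuple(str(f) for f in factor_names)
        if len(set(names)) != len(names):
            raise NamingError(f"factor names must be distinct, got {names}")
        n = len(names)
        masks = [m for m in canonical_masks(n) if m]
        missing = [m for m in masks if m not in beta_by_mask]
        if missing:
            raise IncompleteModelError(
                "saturated parameterization requires all 2^n - 1 exposure terms; "
                "missing: " + ", ".join(term_name(m, names) for m in missing[:8])
            )
        extra = set(beta_by_mask) - set(masks)
        if extra:
            raise SpecificationError(f"unknown term masks {sorted(extra)} for n={n}")
        beta = np.zeros(1 << n)
        for m in masks:
            beta[m] = float(beta_by_mask[m])
        if not np.all(np.isfinite(beta)):
            raise SpecificationError("coefficients must be finite")
        if vcov is not None:
            vcov = np.asarray(vcov, dtype=float)
            t = len(masks)
            if vcov.shape != (t, t):
                raise SpecificationError(
                    f"covariance must be {t}x{t} to match the {t} terms, got {vcov.shape}"
                )
            if not np.allclose(vcov, vcov.T, atol=1e-8):
                raise SpecificationError("covariance matrix is not symmetric (tol 1e-8)")
            if np.any(np.diag(vcov) < 0):
                raise SpecificationError("covariance diagonal has negative entries")
            vcov = (vcov + vcov.T) / 2.0
        self.factor_names = names
        self.beta = beta  # indexed by term mask; index 0 unused (= 0)
        self.vcov = vcov
        self.term_masks = tuple(masks)

    # -- construction helpers -----------------------------------------

    @classmethod
    def from_terms(
        cls,
        terms: Mapping[str, float],
        vcov: Optional[object] = None,
        factor_names: Optional[Sequence[str]] = None,
    ) -> "CoefficientSet":
        """Build from a mapping of term strings (``"A"``, ``"A*B"``) to
        coefficients.  Factor order follows ``factor_names`` when given,
        else the order in which main-effect terms appear.  A DataFrame
        ``vcov`` is aligned by term name; an array is taken in canonical
        term order."""
        if factor_names is None:
            factor_names = [t for t in terms if TERM_SEP not in t]
        names = tuple(factor_names)
        index = {f: i for i, f in enumerate(names)}
        beta_by_mask: dict[int, float] = {}
        for t, value in terms.items():
            mask = 0
            for part in t.split(TERM_SEP):
                part = part.strip()
                if part not in index:
                    raise SpecificationError(
                        f"term {t!r} references unknown factor {part!r}; factors are {names}"
                    )
                mask |= 1 << index[part]
            if mask in beta_by_mask:
                raise SpecificationError(f"duplicate term {t!r}")
            beta_by_mask[mask] = float(value)
        if isinstance(vcov, pd.DataFrame):
            order = [term_name(m, names) for m in canonical_masks(len(names)) if m]
            try:
                vcov = vcov.loc[order, order].to_numpy()
            except KeyError as e:
                raise SpecificationError(f"vcov is missing term {e.args[0]!r}") from None
        return cls(names, beta_by_mask, vcov)

    # -- queries -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.factor_names)

    @property
    def n_terms(self) -> int:
        return len(self.term_masks)

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(term_name(m, self.factor_names) for m in self.term_masks)

    def coefficient(self, term: str) -> float:
        return float(self.beta[self._term_mask(term)])

    def se(self, term: str) -> float:
        if self.vcov is None:
            raise MissingVarianceError("no covariance matrix attached")
        i = self.term_masks.index(self._term_mask(term))
        return float(np.sqrt(self.vcov[i, i]))

    def _term_mask(self, term: str) -> int:
        index = {f: i for i, f in enumerate(self.factor_names)}
        mask = 0
        for part in term.split(TERM_SEP):
            part = part.strip()
            if part not in index:
                raise SpecificationError(f"unknown term {term!r}")
            mask |= 1 << index[part]
        if mask == 0:
            raise SpecificationError("empty term")
        return mask

    def to_frame(self) -> pd.DataFrame:
        rows = {"term": list(self.term_names), "estimate": [float(self.beta[m]) for m in self.term_masks]}
        if self.vcov is not None:
            rows["se"] = list(np.sqrt(np.diag(self.vcov)))
        return pd.DataFrame(rows)

    # -- serialization -------------------------------------------------

    def to_json(self, path=None) -> str:
        d = {
            "factors": list(self.factor_names),
            "terms": list(self.term_names),
            "beta": {t: float(self.beta[m]) for t, m in zip(self.term_names, self.term_masks)},
        }
        if self.vcov is not None:
            d["vcov"] = self.vcov.tolist()
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "CoefficientSet":
        try:
            d = json.loads(path_or_text)
        except (json.JSONDecodeError, TypeError):
            with open(path_or_text) as fh:
                d = json.load(fh)
        vcov = np.asarray(d["vcov"]) if "vcov" in d else None
        return cls.from_terms(d["beta"], vcov=vcov, factor_names=d["factors"])

    def __repr__(self) -> str:
        return (
            f"CoefficientSet(factors={self.factor_names}, terms={self.n_terms}, "
            f"vcov={'yes' if self.vcov is not None else 'no'})"
        )


def write_coefficients(coefset: CoefficientSet, path, vcov_path=None, sep="\t") -> None:
    """Delimited-text export: ``term<sep>estimate`` rows; the covariance, if
    requested, goes to a matrix file with a term-name header row."""
    with open(path, "w") as fh:
        fh.write(f"term{sep}estimate\n")
        for t, m in zip(coefset.term_names, coefset.term_masks):
            fh.write(f"{t}{sep}{coefset.beta[m]:.12g}\n")
    if vcov_path is not None:
        if coefset.vcov is None:
            raise MissingVarianceError("coefficient set has no covariance to write")
        with open(vcov_path, "w") as fh:
            fh.write(sep.join(coefset.term_names) + "\n")
            for row in coefset.vcov:
                fh.write(sep.join(f"{v:.12g}" for v in row) + "\n")


def read_coefficients(path, vcov_path=None, sep="\t") -> CoefficientSet:
    """Read a coefficient file (columns ``term``, ``estimate``) and an
    optional adjacent covariance-matrix file (term-name header row)."""
    df = pd.read_csv(path, sep=sep)
    if not {"term", "estimate"} <= set(df.columns):
        raise SpecificationError(
            f"coefficient file needs columns 'term' and 'estimate', got {list(df.columns)}"
        )
    terms = dict(zip(df["term"].astype(str), df["estimate"].astype(float)))
    vcov = None
    if vcov_path is not None:
        vdf = pd.read_csv(vcov_path, sep=sep)
        vcov = pd.DataFrame(
            vdf.to_numpy(dtype=float), index=list(vdf.columns), columns=list(vdf.columns)
        )
    return CoefficientSet.from_terms(terms, vcov=vcov)


# ---------------------------------------------------------------------
# grid construction and delta method
# ---------------------------------------------------------------------


def rr_grid_from_coefficients(coefset: CoefficientSet) -> RelativeRiskGrid:
    """RR(pattern) = exp( sum of coefficients of every non-empty subset of
    the pattern's present factors ); the all-absent pattern maps to 1."""
    n = coefset.n
    log_rr = coefset.beta.copy()
    # subset-sum (zeta) transform over the n-bit lattice
    for i in range(n):
        bit = 1 << i
        for m in range(1 << n):
            if m & bit:
                log_rr[m] += log_rr[m ^ bit]
    return RelativeRiskGrid(coefset.factor_names, np.exp(log_rr))


def measure_gradient(coefset: CoefficientSet, spec: MeasureSpec) -> np.ndarray:
    """Analytic gradient of a measure with respect to the coefficients, in
    canonical term order.

    For a RERI-family measure M = N/D with N = sum_p c_p RR_p and
    D = RR_d, and RR_p = exp(sum_{T subset of p} beta_T):

        dM/dbeta_T = (sum_{p superset of T} c_p RR_p) / D  -  M * [T subset of d].

    For the multiplicative index I over subset S, log I is the plain sum of
    the product-term coefficients inside S, so dI/dbeta_T = I for every
    term T with \\|T\\| >= 2 contained in S and 0 otherwise.
    """
    if not isinstance(spec, MeasureSpec):
        raise SpecificationError(f"expected a MeasureSpec, got {type(spec).__name__}")
    grid = rr_grid_from_coefficients(coefset)
    rr = grid.values
    if spec.kind is MeasureKind.MULT_INDEX:
        s_mask = grid.subset_mask(spec.subset)
        estimate = evaluate_spec(grid, spec)
        return np.array(
            [
                estimate if (t & ~s_mask) == 0 and bin(t).count("1") >= 2 else 0.0
                for t in coefset.term_masks
            ]
        )
    if spec.kind not in RERI_KINDS:
        raise SpecificationError(f"unknown measure kind {spec.kind!r}")
    form: LinearForm = linear_form(spec, coefset.factor_names)
    d_val = rr[form.denom_mask]
    num = sum(c * rr[m] for m, c in form.coeffs.items())
    estimate = num / d_val
    grad = np.empty(coefset.n_terms)
    for j, t in enumerate(coefset.term_masks):
        n_t = sum(c * rr[m] for m, c in form.coeffs.items() if (t & ~m) == 0)
        grad[j] = n_t / d_val - (estimate if (t & ~form.denom_mask) == 0 else 0.0)
    return grad


def finite_difference_gradient(
    coefset: CoefficientSet, spec: MeasureSpec, step: float = 1e-6
) -> np.ndarray:
    """Central finite differences; verification path for the analytic form."""
    grad = np.empty(coefset.n_terms)
    base = {m: float(coefset.beta[m]) for m in coefset.term_masks}
    for j, t in enumerate(coefset.term_masks):
        vals = []
        for sgn in (+1, -1):
            b = dict(base)
            b[t] += sgn * step
            g = rr_grid_from_coefficients(CoefficientSet(coefset.factor_names, b))
            vals.append(evaluate_spec(g, spec))
        grad[j] = (vals[0] - vals[1]) / (2 * step)
    return grad


def delta_ci(
    coefset: CoefficientSet, spec: MeasureSpec, level: float = 0.95
) -> InteractionMeasure:
    """Point estimate, delta-method SE, and Wald CI for one measure.

    RERI-family intervals are symmetric on the RERI scale; the
    multiplicative index gets a log-scale interval (its log is linear in
    the coefficients, so that interval is exact-Wald rather than a delta
    approximation).
    """
    if coefset.vcov is None:
        raise MissingVarianceError(
            "delta-method intervals need a coefficient covariance matrix"
        )
    if not 0 < level < 1:
        raise SpecificationError(f"confidence level must be in (0,1), got {level}")
    grid = rr_grid_from_coefficients(coefset)
    estimate = evaluate_spec(grid, spec)
    z = stats.norm.ppf(0.5 + level / 2.0)
    if spec.kind is MeasureKind.MULT_INDEX:
        g_log = np.array(
            [
                1.0
                if (t & ~grid.subset_mask(spec.subset)) == 0 and bin(t).count("1") >= 2
                else 0.0
                for t in coefset.term_masks
            ]
        )
        var_log = float(g_log @ coefset.vcov @ g_log)
        if var_log < 0:
            raise NumericalVarianceError(f"negative variance {var_log} for {spec.label()}")
        se_log = np.sqrt(var_log)
        ci = (estimate * np.exp(-z * se_log), estimate * np.exp(z * se_log))
        se = estimate * se_log  # delta-method SE on the index scale
    else:
        g = measure_gradient(coefset, spec)
        var = float(g @ coefset.vcov @ g)
        if var < 0:
            raise NumericalVarianceError(f"negative variance {var} for {spec.label()}")
        se = float(np.sqrt(var))
        ci = (estimate - z * se, estimate + z * se)
    return InteractionMeasure(
        kind=spec.kind,
        subset=spec.subset,
        conditioning=spec.conditioning,
        estimate=estimate,
        se=float(se),
        ci=(float(ci[0]), float(ci[1])),
        level=level,
    )


@dataclass(frozen=True)
class RatioEstimate:
    """A single RR/HR estimand exp(beta_term) with a log-scale Wald CI."""

    term: str
    coefficient: float
    se: Optional[float]
    ratio: float
    ci: Optional[tuple[float, float]]
    level: float = 0.95


def term_ratio_ci(coefset: CoefficientSet, term: str, level: float = 0.95) -> RatioEstimate:
    """exp(b) with CI = exp(b -/+ z*se(b)); matches how HRs are reported."""
    b = coefset.coefficient(term)
    if coefset.vcov is None:
        return RatioEstimate(term, b, None, float(np.exp(b)), None, level)
    se = coefset.se(term)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return RatioEstimate(
        term,
        b,
        se,
        float(np.exp(b)),
        (float(np.exp(b - z * se)), float(np.exp(b + z * se))),
        level,
    )


# ---------------------------------------------------------------------
# fitting from individual-level data
# ---------------------------------------------------------------------


@dataclass
class FittedModel:
    """A saturated-exposure fit: the exposure coefficient block (with its
    covariance sub-matrix) plus covariate estimates kept in a side channel
    (they never enter the RR grid — the grid is covariate-conditional)."""

    coefficients: CoefficientSet
    covariate_estimates: pd.Series
    family: str
    nobs: int
    n_events: int
    log_likelihood: Optional[float] = None


def _term_columns(
    data: pd.DataFrame, exposures: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    names = tuple(exposures)
    n = len(names)
    X = pd.DataFrame(index=data.index)
    term_cols = []
    for m in canonical_masks(n):
        if m == 0:
            continue
        col = term_name(m, names)
        prod = np.ones(len(data))
        for i in range(n):
            if (m >> i) & 1:
                prod = prod * data[names[i]].to_numpy(dtype=float)
        X[col] = prod
        term_cols.append(col)
    return X, term_cols


def _expand_covariates(data: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric covariates pass through; string/categorical covariates are
    one-hot encoded with the first level as reference."""
    out = pd.DataFrame(index=data.index)
    for c in covariates:
        col = data[c]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            out[c] = col.astype(float)
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            out = pd.concat([out, dummies], axis=1)
    return out


def fit_saturated_model(
    data: pd.DataFrame,
    exposures: Sequence[str],
    outcome: Optional[str] = None,
    *,
    time: Optional[str] = None,
    event: Optional[str] = None,
    covariates: Sequence[str] = (),
    family: str = "logistic",
) -> FittedModel:
    """Fit a regression with *all* 2^n - 1 exposure terms plus covariates.

    ``family='logistic'`` needs ``outcome`` (binary column);
    ``family='proportional_hazards'`` needs ``time`` and ``event`` and uses
    Cox regression with the Efron tie correction.  Rows with missing values
    in any used column are dropped (complete-case analysis).  Every one of
    the 2^n exposure patterns must be observed, otherwise the pattern's RR
    — and hence every interaction measure — is not estimable and an
    :class:`UnidentifiableCellError` names the empty cell.
    """
    exposures = list(exposures)
    if family not in ("logistic", "proportional_hazards"):
        raise SpecificationError(
            f"family must be 'logistic' or 'proportional_hazards', got {family!r}"
        )
    if family == "logistic":
        if outcome is None:
            raise SpecificationError("logistic family requires an outcome column")
        used = exposures + list(covariates) + [outcome]
    else:
        if time is None or event is None:
            raise SpecificationError(
                "proportional_hazards family requires time and event columns"
            )
        used = exposures + list(covariates) + [time, event]
    missing_cols = [c for c in used if c not in data.columns]
    if missing_cols:
        raise SpecificationError(f"columns not found in data: {missing_cols}")

    df = data[used].dropna()
    for x in exposures:
        vals = set(pd.unique(df[x]))
        if not vals <= {0, 1, 0.0, 1.0, True, False}:
            raise TypeError(
                f"exposure {x!r} must be binary 0/1; observed values {sorted(vals)[:6]}"
            )
    n = len(exposures)
    masks = np.zeros(len(df), dtype=int)
    for i, x in enumerate(exposures):
        masks |= df[x].to_numpy(dtype=int) << i
    counts = np.bincount(masks, minlength=1 << n)
    for m in range(1 << n):
        if counts[m] == 0:
            raise UnidentifiableCellError(mask_to_string(m, n))

    X_terms, term_cols = _term_columns(df, exposures)
    X_cov = _expand_covariates(df, covariates)
    X = pd.concat([X_terms, X_cov], axis=1)

    if family == "logistic":
        import statsmodels.api as sm

        y = df[outcome].to_numpy(dtype=float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise TypeError(f"outcome {outcome!r} must be binary 0/1")
        Xc = sm.add_constant(X, has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception as e:  # separation, LinAlgError, ...
            raise FitError(f"logistic fit failed: {e}") from e
        if not res.mle_retvals.get("converged", True):
            raise FitError(
                "logistic fit did not converge "
                f"(iterations={res.mle_retvals.get('iterations')}); "
                "check for sparse exposure cells or separation"
            )
        params = res.params
        vcov_full = pd.DataFrame(res.cov_params(), index=Xc.columns, columns=Xc.columns)
        covariate_names = [c for c in Xc.columns if c not in term_cols]
        side = params[covariate_names]
        beta = {t: float(params[t]) for t in term_cols}
        sub_vcov = vcov_full.loc[term_cols, term_cols].to_numpy()
        coefset = CoefficientSet.from_terms(beta, vcov=sub_vcov, factor_names=exposures)
        return FittedModel(
            coefficients=coefset,
            covariate_estimates=side,
            family=family,
            nobs=len(df),
            n_events=int(y.sum()),
            log_likelihood=float(res.llf),
        )

    # Cox proportional hazards
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    fit_df = pd.concat([df[[time, event]].astype(float), X], axis=1)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col=time, event_col=event)
    except (ConvergenceError, Exception) as e:
        if isinstance(e, ConvergenceError) or "converge" in str(e).lower() or isinstance(
            e, np.linalg.LinAlgError
        ):
            raise FitError(f"Cox fit failed: {e}") from e
        raise
    params = cph.params_
    vcov_full = cph.variance_matrix_
    side = params[[c for c in params.index if c not in term_cols]]
    beta = {t: float(params[t]) for t in term_cols}
    sub_vcov = vcov_full.loc[term_cols, term_cols].to_numpy()
    coefset = CoefficientSet.from_terms(beta, vcov=sub_vcov, factor_names=exposures)
    return FittedModel(
        coefficients=coefset,
        covariate_estimates=side,
        family=family,
        nobs=len(fit_df),
        n_events=int(fit_df[event].sum()),
        log_likelihood=float(cph.log_likelihood_),
    )
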