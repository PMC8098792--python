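"""Synthetic-cohort generator and bias/coverage replication harness.

The generator emulates the structure of the worked mortality example:
three binary risk factors at prevalences 0.34 / 0.39 / 0.19, a rare
outcome (about 8% of subjects experience the event), and log-scale
effects that include all two-way product terms and the three-way product
term.  Defaults are calibrated to those values; all of them are plain
config fields.

Outcome schemes
---------------
* ``family='survival'`` (mirrors the worked example's Cox analysis):
  exponential event times with hazard = baseline_hazard * exp(linear
  predictor), administrative censoring at ``max_follow_up`` plus optional
  uniform early censoring.  The true coefficients are log hazard ratios.
* ``family='logistic'`` (fast mode): event probability expit(logit(
  baseline_risk) + linear predictor) — the saturated logistic fit is then
  correctly specified and its coefficients are log odds ratios, which for
  a rare outcome approximate log RRs.  An alternative ``log_binomial``
  scheme draws events with probability baseline_risk * exp(linear
  predictor) and errors out if any pattern's risk exceeds 1.

Randomness: one master seed; each replicate derives its own independent
stream from (seed, replicate_index), so replicates are order-independent
and reproducible individually.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .exceptions import (
    ConfigurationError,
    FitError,
    ScenarioInfeasibleError,
    UnidentifiableCellError,
)
from .grid import mask_to_string
from .measures import (
    MeasureKind,
    MeasureSpec,
    all_conditional_specs,
    evaluate_spec,
)
from .model import CoefficientSet, delta_ci, fit_saturated_model, rr_grid_from_coefficients

# Worked-example calibration: three risk factors, their prevalences, the
# fitted log-hazard coefficients (including all product terms), and the
# observed event fraction.
DEFAULT_FACTORS = ("low_MD", "high_BMI", "smoker")
DEFAULT_PREVALENCES = (0.34, 0.39, 0.19)
DEFAULT_TRUE_BETA = {
    "low_MD": 0.36,
    "high_BMI": 0.29,
    "smoker": 0.41,
    "low_MD*high_BMI": -0.27,
    "low_MD*smoker": -0.23,
    "high_BMI*smoker": -0.24,
    "low_MD*high_BMI*smoker": 0.92,
}
DEFAULT_EVENT_RATE = 0.08
DEFAULT_N_SUBJECTS = 15903


@dataclass
class CovariateConfig:
    """Optional confounders mirroring the worked example's adjustment set:
    one continuous age-like covariate and one 4-level education-like
    covariate (effects on the linear predictor scale)."""

    age_mean: float = 53.4
    age_sd: float = 12.5
    age_effect: float = 0.0
    education_probs: tuple[float, ...] = (0.26, 0.41, 0.18, 0.15)
    education_effects: tuple[float, ...] = (0.0, 0.0, 0.0)  # levels 2..4 vs 1

    def __post_init__(self):
        if abs(sum(self.education_probs) - 1.0) > 1e-9:
            raise ConfigurationError("education level probabilities must sum to 1")
        if len(self.education_effects) != len(self.education_probs) - 1:
            raise ConfigurationError(
                "need one education effect per non-reference level"
            )


@dataclass
class ScenarioConfig:
    """One simulation scenario: exposures, true effects, outcome model,
    and replication settings."""

    factor_names: tuple[str, ...] = DEFAULT_FACTORS
    prevalences: tuple[float, ...] = DEFAULT_PREVALENCES
    true_beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    family: str = "logistic"  # 'logistic' | 'survival'
    outcome_scheme: str = "logit"  # logistic family: 'logit' | 'log_binomial'
    baseline_risk: float = 0.05  # reference-cell event probability (logistic)
    baseline_hazard: float = 0.005  # events per unit time in the reference cell
    max_follow_up: float = 15.0
    censoring_rate: float = 0.0  # fraction subject to uniform early censoring
    n_subjects: int = DEFAULT_N_SUBJECTS
    n_replicates: int = 100
    seed: int = 0
    exposure_corr: Optional[np.ndarray] = None  # latent Gaussian copula correlation
    covariates: Optional[CovariateConfig] = None

    def __post_init__(self):
        self.factor_names = tuple(self.factor_names)
        self.prevalences = tuple(float(p) for p in self.prevalences)
        if len(self.prevalences) != len(self.factor_names):
            raise ConfigurationError("one prevalence per factor required")
        if not all(0 < p < 1 for p in self.prevalences):
            raise ConfigurationError(f"prevalences must be in (0,1), got {self.prevalences}")
        if self.family not in ("logistic", "survival"):
            raise ConfigurationError(f"family must be 'logistic' or 'survival', got {self.family!r}")
        if self.outcome_scheme not in ("logit", "log_binomial"):
            raise ConfigurationError(
                f"outcome_scheme must be 'logit' or 'log_binomial', got {self.outcome_scheme!r}"
            )
        if not 0 < self.baseline_risk < 1:
            raise ConfigurationError("baseline_risk must be in (0,1)")
        if self.baseline_hazard <= 0 or self.max_follow_up <= 0:
            raise ConfigurationError("baseline_hazard and max_follow_up must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigurationError("censoring_rate must be in [0,1)")
        if self.n_subjects < 1 or self.n_replicates < 1:
            raise ConfigurationError("n_subjects and n_replicates must be >= 1")
        if self.exposure_corr is not None:
            corr = np.asarray(self.exposure_corr, dtype=float)
            k = len(self.factor_names)
            if corr.shape != (k, k) or not np.allclose(corr, corr.T):
                raise ConfigurationError("exposure_corr must be a symmetric k x k matrix")
            self.exposure_corr = corr
        # validate the true coefficient set eagerly
        self.coefficient_set()

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    def coefficient_set(self) -> CoefficientSet:
        return CoefficientSet.from_terms(
            dict(self.true_beta), factor_names=self.factor_names
        )

    def pattern_probabilities(self) -> np.ndarray:
        """P(exposure pattern) under independent draws (the default
        generating mechanism; calibration uses this even when a copula is
        configured)."""
        n = self.n_factors
        probs = np.ones(1 << n)
        for m in range(1 << n):
            for i, p in enumerate(self.prevalences):
                probs[m] *= p if (m >> i) & 1 else (1 - p)
        return probs

    def pattern_risks(self) -> np.ndarray:
        """True event probability per exposure pattern (covariates at
        reference), on the configured outcome scheme."""
        log_rr = np.log(rr_grid_from_coefficients(self.coefficient_set()).values)
        if self.family == "survival":
            lam = self.baseline_hazard * np.exp(log_rr)
            return 1.0 - np.exp(-lam * self.max_follow_up)
        if self.outcome_scheme == "log_binomial":
            return self.baseline_risk * np.exp(log_rr)
        return special.expit(special.logit(self.baseline_risk) + log_rr)

    def expected_event_rate(self) -> float:
        return float(self.pattern_probabilities() @ self.pattern_risks())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_beta"] = dict(self.true_beta)
        if self.exposure_corr is not None:
            d["exposure_corr"] = np.asarray(self.exposure_corr).tolist()
        return d

    @classmethod
    def from_toml(cls, path) -> "ScenarioConfig":
        """Load a scenario from a TOML file; keys mirror the field names,
        with ``[true_beta]`` and optional ``[covariates]`` tables."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "covariates" in raw and raw["covariates"] is not None:
            cov = raw["covariates"]
            for key in ("education_probs", "education_effects"):
                if key in cov:
                    cov[key] = tuple(cov[key])
            raw["covariates"] = CovariateConfig(**cov)
        for key in ("factor_names", "prevalences"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "exposure_corr" in raw and raw["exposure_corr"] is not None:
            raw["exposure_corr"] = np.asarray(raw["exposure_corr"], dtype=float)
        return cls(**raw)


def calibrate_baseline(config: ScenarioConfig, target_event_rate: float) -> ScenarioConfig:
    """Return a copy of the scenario whose baseline risk (or hazard) gives
    the target marginal event fraction under independent exposures and
    reference covariates.  Deterministic root-finding, no simulation."""
    if not 0 < target_event_rate < 1:
        raise ConfigurationError("target event rate must be in (0,1)")
    probs = config.pattern_probabilities()
    log_rr = np.log(rr_grid_from_coefficients(config.coefficient_set()).values)
    d = config.to_dict()
    d.pop("covariates", None)
    cov = config.covariates

    if config.family == "survival":
        def rate(lam0):
            return probs @ (1.0 - np.exp(-lam0 * np.exp(log_rr) * config.max_follow_up)) - target_event_rate

        lam0 = optimize.brentq(rate, 1e-12, 100.0 / config.max_follow_up)
        d["baseline_hazard"] = float(lam0)
    elif config.outcome_scheme == "log_binomial":
        b0 = target_event_rate / float(probs @ np.exp(log_rr))
        if b0 * math.exp(float(log_rr.max())) > 1.0:
            raise ConfigurationError(
                "log-binomial risks exceed 1 at the target event rate for pattern "
                f"'{mask_to_string(int(np.argmax(log_rr)), config.n_factors)}'"
            )
        d["baseline_risk"] = float(b0)
    else:
        def rate(logit_b0):
            return probs @ special.expit(logit_b0 + log_rr) - target_event_rate

        d["baseline_risk"] = float(special.expit(optimize.brentq(rate, -30.0, 5.0)))
    return ScenarioConfig(covariates=cov, **d)


def default_scenario(
    seed: int = 0,
    *,
    family: str = "logistic",
    n_subjects: int = DEFAULT_N_SUBJECTS,
    n_replicates: int = 100,
    target_event_rate: float = DEFAULT_EVENT_RATE,
    **overrides,
) -> ScenarioConfig:
    """The worked-example-calibrated scenario: default factors,
    prevalences, and true coefficients, with the baseline calibrated so
    the marginal event fraction matches the target (~8%)."""
    config = ScenarioConfig(
        family=family,
        n_subjects=n_subjects,
        n_replicates=n_replicates,
        seed=seed,
        **overrides,
    )
    return calibrate_baseline(config, target_event_rate)


# ---------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------


def _draw_exposures(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    N, k = config.n_subjects, config.n_factors
    if config.exposure_corr is None:
        return (rng.random((N, k)) < np.asarray(config.prevalences)).astype(np.int8)
    # Gaussian copula: correlated latents thresholded at the prevalence quantiles
    L = np.linalg.cholesky(config.exposure_corr)
    z = rng.standard_normal((N, k)) @ L.T
    return (z < stats.norm.ppf(config.prevalences)).astype(np.int8)


def generate_cohort(config: ScenarioConfig, replicate_index: int = 0) -> pd.DataFrame:
    """Draw one synthetic cohort.

    Columns: one 0/1 column per factor; ``age`` and ``education`` when
    covariates are configured; then ``event`` (logistic family) or
    ``time`` + ``event`` (survival family).  The random stream is fully
    determined by ``(config.seed, replicate_index)``.
    """
    rng = np.random.default_rng([config.seed, replicate_index])
    N, k = config.n_subjects, config.n_factors
    x = _draw_exposures(config, rng)
    masks = (x.astype(int) * (1 << np.arange(k))).sum(axis=1)
    log_rr = np.log(rr_grid_from_coefficients(config.coefficient_set()).values)
    lp = log_rr[masks]

    df = pd.DataFrame({name: x[:, i] for i, name in enumerate(config.factor_names)})
    if config.covariates is not None:
        cov = config.covariates
        age = rng.normal(cov.age_mean, cov.age_sd, N)
        edu = rng.choice(len(cov.education_probs), size=N, p=cov.education_probs) + 1
        lp = lp + cov.age_effect * (age - cov.age_mean)
        for level, eff in enumerate(cov.education_effects, start=2):
            lp = lp + eff * (edu == level)
        df["age"] = age
        df["education"] = pd.Categorical(edu.astype(str))

    if config.family == "survival":
        lam = config.baseline_hazard * np.exp(lp)
        t_event = rng.exponential(1.0 / lam)
        censor = np.full(N, config.max_follow_up)
        if config.censoring_rate > 0:
            early = rng.random(N) < config.censoring_rate
            censor[early] = rng.uniform(0.0, config.max_follow_up, early.sum())
        df["time"] = np.minimum(t_event, censor)
        df["event"] = (t_event <= censor).astype(int)
        return df

    if config.outcome_scheme == "log_binomial":
        p = config.baseline_risk * np.exp(lp)
        if np.any(p > 1.0):
            bad = int(masks[int(np.argmax(p))])
            raise ConfigurationError(
                f"log-binomial event probability exceeds 1 for pattern "
                f"'{mask_to_string(bad, k)}'"
            )
    else:
        p = special.expit(special.logit(config.baseline_risk) + lp)
    df["event"] = (rng.random(N) < p).astype(int)
    return df


# ---------------------------------------------------------------------
# replication study
# ---------------------------------------------------------------------


@dataclass
class MeasureSummary:
    """Monte-Carlo summary for one interaction measure."""

    label: str
    truth: float
    mean_estimate: float
    bias: float
    empirical_se: float
    mean_model_se: float
    coverage: float
    coverage_mc_se: float  # NaN when fewer than 2 usable replicates
    n_replicates: int


@dataclass
class SimulationReport:
    """Bias / coverage report across replicates of one scenario."""

    config: ScenarioConfig
    measures: list[MeasureSummary]
    n_requested: int
    n_used: int
    n_dropped: int
    mean_event_fraction: float
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(m) for m in self.measures]).set_index("label")

    def to_dict(self) -> dict:
        return {
            "scenario": {
                k: v
                for k, v in self.config.to_dict().items()
                if k not in ("exposure_corr", "covariates")
            },
            "n_requested": self.n_requested,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "mean_event_fraction": self.mean_event_fraction,
            "level": self.level,
            "measures": [asdict(m) for m in self.measures],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_tsv(self, path=None) -> str:
        text = self.to_frame().to_csv(sep="\t", float_format="%.6g")
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def default_measure_specs(factor_names: Sequence[str]) -> list[MeasureSpec]:
    """The full worked-report measure set: TotRERI, the top-order RERI,
    and every conditional lower-order RERI in every stratum (8 measures
    for three factors)."""
    names = tuple(factor_names)
    return [
        MeasureSpec(MeasureKind.TOT_RERI, names),
        MeasureSpec(MeasureKind.RERI_TOP, names),
        *all_conditional_specs(names),
    ]


def run_simulation_study(
    config: ScenarioConfig,
    measure_specs: Optional[Sequence[MeasureSpec]] = None,
    level: float = 0.95,
) -> SimulationReport:
    """Generate–fit–measure over all replicates and aggregate bias,
    empirical vs model-based SE, and CI coverage per measure.

    Truth is computed analytically from the true coefficients.  Replicates
    whose saturated fit fails (empty exposure cell, separation,
    non-convergence) are dropped and counted; more than 20% dropped raises
    :class:`ScenarioInfeasibleError`.
    """
    specs = list(measure_specs) if measure_specs is not None else default_measure_specs(
        config.factor_names
    )
    true_grid = rr_grid_from_coefficients(config.coefficient_set())
    truths = np.array([evaluate_spec(true_grid, s) for s in specs])

    covariate_cols = (
        ["age", "education"] if config.covariates is not None else []
    )
    estimates: list[np.ndarray] = []
    ses: list[np.ndarray] = []
    covered: list[np.ndarray] = []
    event_fracs: list[float] = []
    dropped = 0
    for rep in range(config.n_replicates):
        cohort = generate_cohort(config, rep)
        try:
            if config.family == "survival":
                fitted = fit_saturated_model(
                    cohort,
                    config.factor_names,
                    time="time",
                    event="event",
                    covariates=covariate_cols,
                    family="proportional_hazards",
                )
            else:
                fitted = fit_saturated_model(
                    cohort,
                    config.factor_names,
                    outcome="event",
                    covariates=covariate_cols,
                    family="logistic",
                )
        except (UnidentifiableCellError, FitError):
            dropped += 1
            continue
        ms = [delta_ci(fitted.coefficients, s, level=level) for s in specs]
        estimates.append(np.array([m.estimate for m in ms]))
        ses.append(np.array([m.se for m in ms]))
        covered.append(
            np.array([m.ci[0] <= t <= m.ci[1] for m, t in zip(ms, truths)], dtype=float)
        )
        event_fracs.append(float(cohort["event"].mean()))

    n_used = len(estimates)
    if dropped > 0.2 * config.n_replicates or n_used == 0:
        raise ScenarioInfeasibleError(
            f"{dropped}/{config.n_replicates} replicates dropped "
            "(unidentifiable cells or failed fits); scenario is infeasible "
            "at this sample size"
        )
    est = np.vstack(estimates)
    se = np.vstack(ses)
    cov = np.vstack(covered)
    summaries = []
    for j, spec in enumerate(specs):
        coverage = float(cov[:, j].mean())
        summaries.append(
            MeasureSummary(
                label=spec.label(),
                truth=float(truths[j]),
                mean_estimate=float(est[:, j].mean()),
                bias=float(est[:, j].mean() - truths[j]),
                empirical_se=float(est[:, j].std(ddof=1)) if n_used > 1 else float("nan"),
                mean_model_se=float(se[:, j].mean()),
                coverage=coverage,
                coverage_mc_se=(
                    float(np.sqrt(coverage * (1 - coverage) / n_used))
                    if n_used > 1
                    else float("nan")
                ),
                n_replicates=n_used,
            )
        )
    return SimulationReport(
        config=config,
        measures=summaries,
        n_requested=config.n_replicates,
        n_used=n_used,
        n_dropped=dropped,
        mean_event_fraction=float(np.mean(event_fracs)),
        level=level,
    )
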