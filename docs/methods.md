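# Methods

This note documents the statistical machinery behind `multireri`: the
measures and the identities they satisfy, the variance model, the two
estimation pathways, the synthetic-data generator, and the numerical and
design choices that were genuinely open.

## Measures and identities

Let `X_1 … X_n` be binary risk factors, and `RR_p` the relative risk of
the outcome for exposure pattern `p ∈ {0,1}^n` against the all-absent
reference (`RR_0 = 1`). Excess relative risk is `ERR_p = RR_p − 1`.
All additive-interaction measures implemented here are of the form

```
M = ( Σ_p c_p · RR_p ) / RR_d
```

with integer coefficients `c_p` from an inclusion–exclusion expansion
and a single re-referencing pattern `d` (`d = 0`, i.e. divide by 1, for
unconditional measures):

| measure | definition |
|---|---|
| `TotRERI_n` | `RR(all) − Σ_i RR(only i) + (n−1)` |
| `RERI_n` (top order) | `Σ_S (−1)^{n−|S|} RR(S)` over all `2^n` subsets |
| `RERI_k(S | z)` | `[ Σ_{s⊆S} (−1)^{|S|−|s|} RR(s ∪ z⁺) ] / RR(z⁺)` |
| `I` (multiplicative) | `RR(joint) / Π RR(single)` |

where `z⁺` is the set of conditioning factors fixed *present*. Two exact
identities hold for every positive grid and are enforced by property
tests rather than re-derivation in code:

* **Decomposition.** `TotRERI_n = RERI_n + Σ_{2≤|S|<n} RERI_|S|(S | rest
  absent)`. The proof is a binomial cancellation: in the summed
  inclusion–exclusion coefficients, every `RR_T` with `2 ≤ |T| < n`
  receives `Σ_j C(n−t, j)(−1)^j = 0`, singletons receive −1, the full
  pattern +1, and the reference `n−1`.
* **Pivot recursion** (n ≥ 3). For any factor `i`:
  `RERI_n = RERI_{n−1}(rest | i present)·RR(only i) − RERI_{n−1}(rest | i absent)`,
  i.e. the top-order interaction is the contrast of the lower-order
  interaction across the strata of any one factor.

Sign classification (super-/sub-additive) uses a default tolerance of 0
— classification is by sign, as the measures are defined — with an
optional numeric tolerance for near-zero estimates.

The multiplicative index is printed for two factors in the classical
literature; the generalized ratio over any subset is implemented as the
natural extension (its log is a plain sum of product-term coefficients).
With all single-factor RRs ≥ 1, `I ≥ 1 ⇒ TotRERI ≥ 0` and
`TotRERI ≤ 0 ⇒ I ≤ 1` (AM–GM-type inequality `Π(1+e_i) ≥ 1+Σe_i`);
this direction is property-tested. No multiplicative analogue of the
additive decomposition is defined or implemented.

## Orientation of factors

All measures presuppose risk-oriented factors. A protective factor
(single-factor RR < 1, judged at the reference of the others) breaks the
additivity benchmark — summing excess risks of protective factors can
imply negative joint RRs. `check_risk_orientation` flags such factors
and the reporting pipeline refuses to compute RERIs until they are
recoded (`reorient`: bit-flip the factor in every pattern and re-
reference the grid) or the user overrides explicitly. An optional strict
check within strata is deliberately *not* automated further: under
qualitative interaction no orientation makes every factor risk-conferring
in every stratum, and the tool reports rather than guesses.

## Variance model

### From regression coefficients

A saturated exposure parameterization — one log-scale coefficient
`β_T` per non-empty factor subset `T` — gives
`log RR_p = Σ_{T⊆p} β_T`. For any measure `M = N/D` as above,

```
∂M/∂β_T = ( Σ_{p ⊇ T} c_p RR_p ) / RR_d  −  M · 1[T ⊆ d],
```

so gradients are analytic; a central finite-difference path (step 1e−6)
exists purely for verification and the two agree to 1e−6 relative in
tests. SEs are `√(gᵀ V g)` with `V` the coefficient covariance.
Intervals are Wald: symmetric on the RERI scale for RERI-family
measures, log-scale (asymmetric) for single RR/HR estimands and for the
multiplicative index (whose log is linear in β, making that interval
exact-Wald). The normal quantile is computed exactly, not hard-coded
1.96. A negative quadratic form raises rather than silently clipping.

Model fitting always includes every product term: with any term dropped,
some pattern RRs — and therefore the measures — are not estimable.
Logistic fits use maximum likelihood (statsmodels); survival fits use
Cox partial likelihood with the Efron tie approximation (lifelines
default; a standard choice, no substantive grounds to deviate).
Covariates enter the linear predictor (continuous as-is, categorical
one-hot) but never the grid: the RR grid is covariate-conditional.
Every one of the 2^n exposure patterns must be observed; an empty cell
raises an error naming the pattern instead of returning a silently
non-identified fit.

### From contingency tables

With per-pattern cases `a_p` and denominators `N_p`, risks are
`a_p/N_p` (rates for person-time denominators) and the standard
large-sample variances of the log effect per cell are
`1/a_p − 1/N_p` (subject counts), `1/a_p` (person-time), or
`1/a_p + 1/(N_p−a_p)` (odds mode for case–control input, emitted with a
rare-disease warning). Cells are independent; log-RRs still co-vary
through the shared reference cell. Rather than treating measures as
functions of correlated log-RRs directly, the log-RRs are Möbius-
inverted into the saturated coefficient vector (`β_T = Σ_{s⊆T}
(−1)^{|T|−|s|} log RR_s` — exactly the saturated log-linear estimate)
and the per-cell variances are pushed through that linear map, giving a
full coefficient covariance including the reference-cell contribution.
Delta-method SEs then reuse the regression pathway unchanged. In odds
mode this reproduces a saturated logistic regression exactly (point
estimates and SEs), which is tested.

A zero-case non-reference cell makes a log-RR variance infinite (and
the RR zero, which no valid grid can hold); the optional continuity
correction adds 0.5 to every cell when any cell is degenerate. It is
off by default — it biases estimates slightly in the common non-
degenerate case — and always warned/logged when applied.

## Synthetic-data generator

The generator emulates the structure of the worked mortality cohort:

* three binary factors at prevalences **0.34 / 0.39 / 0.19**
  (independent Bernoulli by default; optionally a latent Gaussian-copula
  correlation for dependence scenarios — a copula rather than pairwise
  odds-ratio specification, because it defines a coherent joint
  distribution at any n);
* true effects equal to the worked example's seven log-hazard
  coefficients (0.36, 0.29, 0.41, −0.27, −0.23, −0.24, 0.92);
* a rare outcome: the baseline risk/hazard is calibrated by
  deterministic root-finding so the marginal event fraction is **8%**
  (the worked cohort's mortality), at the default N = 15,903;
* optional covariates mirroring the worked adjustment set: one normal
  age-like confounder (mean 53.4, SD 12.5) and one 4-level
  education-like category (probabilities 0.26/0.41/0.18/0.15).

Outcome schemes:

* **survival** (mirrors the worked Cox analysis): exponential event
  times with hazard `λ_0·exp(linear predictor)`, administrative
  censoring at `max_follow_up` plus optional uniform early censoring.
  The Cox fit is then correctly specified.
* **logistic** (fast mode, default for the replication studies):
  `P(event) = expit(logit(p_0) + linear predictor)`, making the
  saturated logistic fit correctly specified; its coefficients are log
  odds ratios, which at 8% events approximate log RRs. Coverage is
  evaluated against the generating coefficients, so the evaluation is
  internally consistent rather than resting on the rare-disease
  approximation.
* **log-binomial** option: `P(event) = p_0·exp(linear predictor)`, with
  a configuration error naming the offending pattern if any risk
  exceeds 1.

What the generator does **not** emulate: real covariate–exposure
confounding structure, non-proportional hazards, measurement error,
informative censoring, or missing data. Passing bias/coverage tests
therefore demonstrate correctness of the estimators and variance
formulas under a correctly specified model, not robustness to the
misspecifications real cohorts carry.

Randomness: each replicate's generator is seeded with
`(master_seed, replicate_index)` via numpy's `SeedSequence`, so
replicates are order-independent and individually reproducible, and
reports are byte-identical given (seed, config).

## Replication harness

`run_simulation_study` generates, refits (dropping and counting
replicates with empty cells or failed fits; >20% dropped aborts the
scenario as infeasible), computes all eight worked-report measures with
delta CIs, and aggregates per measure: analytic truth, mean estimate,
bias, empirical SE, mean model SE, CI coverage, and the binomial
Monte-Carlo SE of coverage (flagged NaN for a single replicate).

Problem sizes used by the shipped checks: the algebraic property sweep
runs 1,000 random grids at each n = 2…6; the bootstrap comparison uses
one N = 20,000 cohort with 200 resamples (delta vs bootstrap SEs agree
within 15%); the bias/coverage study runs 500 replicates at N = 20,000
in logistic mode. The three-point consistency ladder (N = 2,000 /
20,000 / 200,000) checks that bias shrinks with sample size.

## Known limitations

* Binary exposures only; ordinal/continuous exposures need different
  machinery and are out of scope.
* Case–control input is supported only through odds-ratio mode with the
  rare-disease caveat; no design-specific corrections.
* The contingency pathway offers no stratified (Mantel–Haenszel-type)
  pooling; confounder adjustment belongs to the model pathway.
* Qualitative interaction is reported (mixed orientation warnings), not
  formally tested.
* Grids are dense over 2^n patterns, capped at n = 16; in practice
  estimation is limited far earlier by cell counts, and the tool errors
  on any empty cell rather than extrapolating.
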