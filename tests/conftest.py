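import numpy as np
import pytest

from multireri import RelativeRiskGrid
from multireri.examples import mortality_example

# Published worked-example values: log-hazard coefficients of the
# diet/obesity/smoking mortality analysis and the interaction measures the
# original report derived from them (all rounded to two decimals there).
PRINTED_HRS = {
    "low_MD": 1.43,
    "high_BMI": 1.34,
    "smoker": 1.51,
    "low_MD*high_BMI": 0.77,
    "low_MD*smoker": 0.79,
    "high_BMI*smoker": 0.79,
    "low_MD*high_BMI*smoker": 2.51,
}
PRINTED_RERIS = {
    "RERI_2(low_MD,high_BMI | smoker=0)": -0.30,
    "RERI_2(low_MD,smoker | high_BMI=0)": -0.23,
    "RERI_2(high_BMI,smoker | low_MD=0)": -0.25,
    "RERI_2(low_MD,high_BMI | smoker=1)": 1.11,
    "RERI_2(low_MD,smoker | high_BMI=1)": 1.31,
    "RERI_2(high_BMI,smoker | low_MD=1)": 1.20,
    "RERI_3(low_MD,high_BMI,smoker)": 1.98,
    "TotRERI_3(low_MD,high_BMI,smoker)": 1.20,
}


@pytest.fixture(scope="session")
def worked_coefs():
    return mortality_example()


@pytest.fixture(scope="session")
def worked_grid(worked_coefs):
    from multireri import rr_grid_from_coefficients

    return rr_grid_from_coefficients(worked_coefs)


def random_grid(rng: np.random.Generator, n: int, scale: float = 0.7,
                risk_oriented: bool = False) -> RelativeRiskGrid:
    """Random positive RR grid; with ``risk_oriented`` the single-factor
    RRs are forced >= 1."""
    rr = np.exp(rng.normal(0.0, scale, 1 << n))
    rr[0] = 1.0
    if risk_oriented:
        for i in range(n):
            rr[1 << i] = np.exp(abs(rng.normal(0.0, scale)))
    names = [f"X{i + 1}" for i in range(n)]
    return RelativeRiskGrid(names, rr)


def additive_grid(e: np.ndarray) -> RelativeRiskGrid:
    """Exactly additive grid: RR(S) = 1 + sum of the excess risks in S."""
    n = len(e)
    rr = np.ones(1 << n)
    for m in range(1 << n):
        rr[m] = 1.0 + sum(e[i] for i in range(n) if (m >> i) & 1)
    return RelativeRiskGrid([f"X{i + 1}" for i in range(n)], rr)
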