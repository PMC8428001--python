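import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nhstcheck import (
    NS,
    CheckConfig,
    NhstResult,
    PInterval,
    ReportedNumber,
    TestFamily,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

TWO_SIDED = (TestFamily.t, TestFamily.Z, TestFamily.r)
UPPER_TAIL = (
    TestFamily.F,
    TestFamily.chi2,
    TestFamily.Q,
    TestFamily.Q_between,
    TestFamily.Q_within,
)
ALL_FAMILIES = TWO_SIDED + UPPER_TAIL


def random_result(rng: np.random.Generator) -> NhstResult:
    """One random syntactically valid NHST result, any family and claim style."""
    family = ALL_FAMILIES[int(rng.integers(0, len(ALL_FAMILIES)))]
    stat_dec = int(rng.integers(1, 4))
    df1 = df2 = None
    if family is TestFamily.t:
        value = float(rng.uniform(-5, 5))
        df1 = int(rng.integers(2, 300))
    elif family is TestFamily.Z:
        value = float(rng.uniform(-5, 5))
    elif family is TestFamily.r:
        value = float(rng.uniform(-0.94, 0.94))
        df1 = int(rng.integers(3, 200))
    elif family is TestFamily.F:
        value = float(rng.uniform(0.01, 20))
        df1 = int(rng.integers(1, 12))
        df2 = int(rng.integers(5, 300))
    else:
        df1 = int(rng.integers(1, 30))
        value = float(rng.uniform(0.05, 3.0 * df1))
    value = round(value, stat_dec)
    statistic = ReportedNumber(value=value, op="=", decimals=stat_dec)

    style = rng.random()
    if style < 0.10:
        p_claim = NS
    else:
        dec = int(rng.integers(1, 4))
        op = ["=", "<", ">"][int(rng.integers(0, 3))]
        p_val = round(float(rng.uniform(0, 1)), dec)
        p_claim = ReportedNumber(value=p_val, op=op, decimals=dec)
    return NhstResult(
        family=family, statistic=statistic, p_reported=p_claim, df1=df1, df2=df2
    )


def oracle_classify(result: NhstResult, pint: PInterval, config: CheckConfig) -> str:
    """Brute-force verdict: scan a dense grid of p* over [p_lo, p_hi].

    Independent of the analytic interval-overlap logic in the package: the
    numeric claim is tested pointwise on 2001 grid values.
    """

    def satisfied(band: PInterval) -> bool:
        if result.is_ns:
            return band.p_point > config.alpha
        p = result.p_reported
        if p.op == "=":
            if p.value == 0.0 and config.zero_p_always_inconsistent:
                return False
            grid = np.linspace(band.p_lo, band.p_hi, 2001)
            scale = 10.0**p.decimals
            rounded = np.floor(grid * scale + 0.5) / scale
            return bool(np.any(np.abs(rounded - p.value) < 1e-9))
        grid = np.linspace(band.p_lo, band.p_hi, 2001)
        if p.op == "<":
            return bool(np.any(grid < p.value))
        return bool(np.any(grid > p.value))

    if satisfied(pint):
        return "consistent"
    # severity
    if result.is_ns:
        rep_sig = False
    else:
        p = result.p_reported
        if p.op == "=":
            rep_sig = p.value < config.alpha
        elif p.op == "<":
            rep_sig = True if p.value <= config.alpha else None
        else:
            rep_sig = False if p.value >= config.alpha else None
    rec_sig = pint.p_point < config.alpha
    if rep_sig is not None and rep_sig != rec_sig:
        return "gross"
    return "inconsistent"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180101)
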