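import numpy as np
import pytest

from isletsort import default_sc_islet_config, simulate_events


@pytest.fixture(scope="session")
def default_config():
    return default_sc_islet_config(seed=12345)


@pytest.fixture(scope="session")
def day7_table(default_config):
    """One 10,000-event day-7 table shared by read-only tests."""
    return simulate_events(default_config, 10000, 7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (deliberately naive re-implementations)
# ---------------------------------------------------------------------------

def quantile_oracle(values, p):
    """p-quantile by direct rank interpolation: rank 1 + p*(n-1) on the
    sorted sample, linearly interpolated between order statistics."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = p * (n - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    frac = h - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def rpi_oracle(alpha_values, beta_values):
    """RPI recomputed from raw values via the quantile oracle."""
    p95 = quantile_oracle(alpha_values, 0.95)
    q1 = quantile_oracle(beta_values, 0.25)
    q3 = quantile_oracle(beta_values, 0.75)
    if q3 == q1:
        return 0.0 if p95 < q1 else 1.0
    return min(1.0, max(0.0, (p95 - q1) / (q3 - q1)))
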