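import numpy as np
import pytest

import fhrsentinel as fs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ar1(rng, n, phi, sd=1.0):
    """Gaussian AR(1) with marginal sd ``sd`` and per-sample coefficient ``phi``."""
    innov = rng.standard_normal(n) * sd * np.sqrt(1 - phi ** 2)
    x = np.empty(n)
    x[0] = sd * rng.standard_normal()
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i]
    return x


@pytest.fixture(scope="session")
def default_cohort():
    """The default 14-recording synthetic cohort (one fixed master seed)."""
    return fs.simulate_cohort(14, master_seed=20260921)


@pytest.fixture(scope="session")
def default_cohort_analysis(default_cohort):
    """Full pipeline (features -> LT -> normalization -> distance -> sentinel
    -> pressure-based decompensation) on the default cohort.

    Session-scoped: the nearest-neighbor entropy estimation over all windows
    dominates the suite's runtime, so it is computed once.
    """
    return fs.analyze_cohort(default_cohort)
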