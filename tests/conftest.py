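import numpy as np
import pytest

from morphograd import fcs_core as fcs
from morphograd import synthetic_embryo as emb


@pytest.fixture(scope="session")
def multi_tau_lags():
    """A realistic quasi-log lag grid (20 us base, up to ~1 s)."""
    grid = fcs.multi_tau_lag_grid(500_000, 2e-5, max_lag=1.0)
    return np.array([g[0] for g in grid])


@pytest.fixture(scope="session")
def exact_2c_curve(multi_tau_lags):
    """Noise-free two-component curve with known parameters."""
    model = fcs.FcsModel.two_component(
        n_particles=0.8, dwell_fast=1.8e-4, dwell_slow=2.5e-3,
        fraction_fast=0.93)
    return fcs.CorrelationCurve(multi_tau_lags,
                                fcs.model_g(model, multi_tau_lags)), model


@pytest.fixture(scope="session")
def phantoms():
    """Ten default synthetic embryos (session-cached: sampling only)."""
    return [emb.make_phantom(seed) for seed in range(10)]


def direct_autocorrelation(counts, ks):
    """Brute-force O(n^2) symmetric-normalized autocorrelation oracle.

    Plain python loops; deliberately independent of the package's
    vectorized multi-tau implementation.
    """
    out = []
    n = len(counts)
    for k in ks:
        s = 0.0
        mh = 0.0
        mt = 0.0
        for i in range(n - k):
            s += counts[i] * counts[i + k]
            mh += counts[i]
            mt += counts[i + k]
        m = n - k
        out.append(s / m / ((mh / m) * (mt / m)) - 1.0)
    return np.array(out)
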