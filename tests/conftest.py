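"""Shared fixtures and independent numerical oracles."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from flimmetab.synth import AcquisitionConfig


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


def convolution_oracle(params, edges, period, dt=1e-4, n_periods=12):
    """Brute-force expected bin counts: exponential decay density convolved
    with a discretized Gaussian on a fine grid, wrapped over ``n_periods``
    pulse periods and integrated per bin from the cumulative sum.

    Independent of the closed-form path: no erfc/erfcx, plain quadrature.
    """
    n_t = int(round(period / dt))
    # one period before the pulse: Gaussian jitter can pull arrivals to
    # negative times, which wrap to the end of the previous period
    t = (np.arange((n_periods + 1) * n_t) + 0.5) * dt - period
    out = np.zeros(len(edges) - 1)
    for a, tau in ((params.a1, params.tau1), (params.a2, params.tau2)):
        if a == 0:
            continue
        u = t - params.t0
        dens = np.where(u >= 0, np.exp(-np.maximum(u, 0) / tau) / tau, 0.0)
        if params.sigma > 0:
            m = int(np.ceil(10 * params.sigma / dt))
            s = np.arange(-m, m + 1) * dt
            g = np.exp(-0.5 * (s / params.sigma) ** 2)
            g /= g.sum()
            dens = fftconvolve(dens, g, mode="same")
        wrapped = dens.reshape(n_periods + 1, n_t).sum(axis=0)
        cdf = np.concatenate(([0.0], np.cumsum(wrapped) * dt))
        tgrid = np.arange(n_t + 1) * dt
        out += a * np.diff(np.interp(edges, tgrid, cdf))
    return out
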