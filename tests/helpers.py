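"""Shared helpers for the test suite."""

import numpy as np

from ecoaf.core_io import TimeSeries


def make_ts(values, times=None, names=None):
    """Build a TimeSeries from a 1-D or 2-D array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    m, n = values.shape
    if times is None:
        times = np.arange(n, dtype=float)
    if names is None:
        names = [f"x{i}" for i in range(m)]
    return TimeSeries(np.asarray(times, dtype=float), values, names)


def gen_ar1(seed, n=600, phi=0.5, sigma_shift_at=None, shift_factor=2.0):
    """AR(1) series; optionally the innovation sd jumps at an index."""
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n)
    x = np.zeros(n)
    for i in range(1, n):
        s = shift_factor if (sigma_shift_at is not None and i >= sigma_shift_at) else 1.0
        x[i] = phi * x[i - 1] + s * e[i]
    return x
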