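"""Seeded synthetic generators: seasonally forced disturbed series (a
stand-in for monthly vegetation-index data around a wildfire), 1/f^beta
colored noise, random Boolean networks, and flow-network fixtures.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ecoaf.antifragility import BooleanNetwork
from ecoaf.ascendancy import FlowNetwork
from ecoaf.core_io import TimeSeries

__all__ = [
    "DisturbanceSpec",
    "gen_seasonal_disturbance",
    "gen_colored_noise",
    "gen_rbn",
    "gen_flow_network",
]


@dataclass(frozen=True)
class DisturbanceSpec:
    """An abrupt drop with exponential (possibly partial) recovery.

    ``drop`` and ``permanent_offset`` are fractions of the seasonal mean
    level; permanent_offset = 0 means full recovery, > 0 a lasting
    deficit.
    """

    time: float
    drop: float
    recovery_rate: float = 0.1
    permanent_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop <= 1.0:
            raise ValueError("drop must be in [0, 1]")
        if self.recovery_rate < 0:
            raise ValueError("recovery_rate must be >= 0")
        if not 0.0 <= self.permanent_offset <= self.drop:
            raise ValueError("need 0 <= permanent_offset <= drop")


def gen_seasonal_disturbance(
    n: int,
    f: float,
    alpha: float,
    gammas,
    deltas,
    dist: DisturbanceSpec | None = None,
    sigma: float = 0.0,
    seed: int = 0,
    name: str = "NDVI",
) -> tuple[TimeSeries, np.ndarray]:
    """Harmonic seasonal signal with an optional disturbance and noise.

    y_t = alpha + sum_j gammas[j]*sin(2*pi*(j+1)*t/f + deltas[j])
          - deficit(t) + N(0, sigma^2)

    with deficit(t >= t_d) = alpha * (offset + (drop - offset) *
    exp(-rate*(t - t_d))). The deficit hits the deterministic component
    only, so the returned truth trajectory is exact.

    Returns
    -------
    (TimeSeries, ndarray)
        The series (t = 0, 1, ..., n-1) and the deficit trajectory
        (the generator truth; zeros before the disturbance).
    """
    n = int(n)
    if n < 2 * f:
        raise ValueError(f"need n >= 2*f = {2 * f} samples (two seasonal cycles)")
    gammas = np.asarray(gammas, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    if gammas.size != deltas.size:
        raise ValueError("gammas and deltas must have equal length")
    t = np.arange(n, dtype=float)
    y = np.full(n, float(alpha))
    for j, (g, d) in enumerate(zip(gammas, deltas), start=1):
        y += g * np.sin(2.0 * np.pi * j * t / f + d)
    deficit = np.zeros(n)
    if dist is not None:
        after = t >= dist.time
        tau = t[after] - dist.time
        deficit[after] = alpha * (
            dist.permanent_offset + (dist.drop - dist.permanent_offset) * np.exp(-dist.recovery_rate * tau)
        )
    y = y - deficit
    if sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, sigma, size=n)
    meta = {"generator": "gen_seasonal_disturbance", "f": f, "alpha": alpha, "sigma": sigma, "seed": seed}
    if dist is not None:
        meta["disturbance"] = {
            "time": dist.time,
            "drop": dist.drop,
            "recovery_rate": dist.recovery_rate,
            "permanent_offset": dist.permanent_offset,
        }
    return TimeSeries(t, y[None, :], [name], meta=meta), deficit


def gen_colored_noise(n: int, beta: float, seed: int = 0) -> np.ndarray:
    """1/f^beta noise by spectral synthesis, standardized to mean 0, sd 1.

    A Gaussian-amplitude, random-phase spectrum is shaped by f^(-beta/2)
    and inverse-transformed, giving the target log-log spectral slope in
    expectation with no burn-in.
    """
    n = int(n)
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n)
    spectrum = np.zeros(freqs.size, dtype=complex)
    nf = freqs.size - 1  # nonzero frequencies
    amp = freqs[1:] ** (-beta / 2.0)
    re = rng.standard_normal(nf)
    im = rng.standard_normal(nf)
    spectrum[1:] = amp * (re + 1j * im)
    x = np.fft.irfft(spectrum, n=n)
    x = x - x.mean()
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate synthesis")
    return x / sd


def gen_rbn(N: int, K: int, bias: float = 0.5, seed: int = 0) -> BooleanNetwork:
    """Random Boolean network: K distinct random inputs per node, truth
    tables iid Bernoulli(bias), random initial state."""
    N = int(N)
    K = int(K)
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= K <= N:
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not 0.0 <= bias <= 1.0:
        raise ValueError("bias must be in [0, 1]")
    rng = np.random.default_rng(seed)
    inputs = [rng.choice(N, size=K, replace=False) for _ in range(N)]
    tables = [(rng.random(2**K) < bias).astype(np.int8) for _ in range(N)]
    state = rng.integers(0, 2, size=N).astype(np.int8)
    return BooleanNetwork(N=N, inputs=inputs, tables=tables, state=state)


def gen_flow_network(n: int, structure: str = "random", seed: int = 0) -> FlowNetwork:
    """Flow-network fixtures with known information content.

    independent : rank-one flows (zero mutual information)
    diagonal    : a random permutation matrix (AMI = log2 n)
    chain       : unit flows i -> i+1
    random      : iid positive flows
    """
    n = int(n)
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    labels = [f"c{i}" for i in range(n)]
    if structure == "independent":
        u = rng.uniform(0.5, 1.5, size=n)
        v = rng.uniform(0.5, 1.5, size=n)
        F = np.outer(u, v)
    elif structure == "diagonal":
        perm = rng.permutation(n)
        F = np.zeros((n, n))
        F[np.arange(n), perm] = 1.0
    elif structure == "chain":
        F = np.zeros((n, n))
        F[np.arange(n - 1), np.arange(1, n)] = 1.0
    elif structure == "random":
        F = rng.uniform(0.1, 1.0, size=(n, n))
    else:
        raise ValueError(f"unknown structure {structure!r}")
    return FlowNetwork(labels, F)
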