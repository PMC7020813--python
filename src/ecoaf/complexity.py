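"""Emergence, self-organization and complexity measures, plus the 1/f^beta
spectral exponent and noise-archetype classification.

Emergence E is normalized Shannon information of a state distribution,
self-organization is its complement S = 1 - E, and complexity
C = 4*E*S peaks where order and variability balance. For real-valued
series the state distribution comes from Bandt-Pompe ordinal patterns
(permutation entropy). The spectral exponent beta of 1/f^beta
fluctuations classifies dynamics against the archetypal noise groups:
white (beta ~ 0), pink (beta ~ 1, the criticality fingerprint) and
Brownian (beta ~ 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.signal import welch
from scipy.stats import linregress

__all__ = [
    "ProbabilityVector",
    "ComplexityTriple",
    "emergence",
    "complexity_triple",
    "permutation_entropy",
    "ordinal_distribution",
    "binary_complexity",
    "spectral_exponent",
    "classify_noise",
]

NOISE_ARCHETYPES = {"white": 0.0, "pink": 1.0, "brown": 2.0}


@dataclass(frozen=True)
class ProbabilityVector:
    """A distribution over K >= 2 categories."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.size < 2:
            raise ValueError("need at least 2 categories")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")


@dataclass(frozen=True)
class ComplexityTriple:
    """Emergence, self-organization and complexity, all in [0, 1]."""

    E: float
    S: float
    C: float

    def __post_init__(self) -> None:
        for name, v in (("E", self.E), ("S", self.S), ("C", self.C)):
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.S - (1.0 - self.E)) > 1e-9:
            raise ValueError("S must equal 1 - E")
        if abs(self.C - 4.0 * self.E * self.S) > 1e-9:
            raise ValueError("C must equal 4*E*S")


def emergence(p: ProbabilityVector | np.ndarray, base_K: int | None = None) -> float:
    """Normalized Shannon information E = H(p) / log(base_K) in [0, 1].

    ``base_K`` is the declared alphabet size (defaults to the number of
    categories in ``p``); unobserved-but-possible states lower E.
    """
    if not isinstance(p, ProbabilityVector):
        p = ProbabilityVector(np.asarray(p, dtype=float))
    if base_K is None:
        base_K = p.p.size
    if base_K < 2:
        raise ValueError("base_K must be >= 2")
    pos = p.p[p.p > 0]
    if pos.size > base_K:
        raise ValueError(f"{pos.size} occupied categories exceed alphabet size {base_K}")
    h = -float(np.sum(pos * np.log2(pos)))
    return h / math.log2(base_K)


def complexity_triple(E: float) -> ComplexityTriple:
    """Build the (E, S, C) triple from an emergence value: S = 1 - E, C = 4*E*S."""
    if not -1e-9 <= E <= 1 + 1e-9:
        raise ValueError(f"emergence {E} outside [0, 1]")
    E = min(max(E, 0.0), 1.0)
    S = 1.0 - E
    return ComplexityTriple(E=E, S=S, C=4.0 * E * S)


def ordinal_distribution(x: np.ndarray, order: int = 3, delay: int = 1) -> ProbabilityVector:
    """Bandt-Pompe ordinal-pattern distribution over all d! patterns.

    Ties are broken by temporal index (stable argsort). The returned
    vector has length ``order!`` including never-seen patterns.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    d = int(order)
    tau = int(delay)
    if not 2 <= d <= 7:
        raise ValueError("order must be in 2..7")
    if tau < 1:
        raise ValueError("delay must be >= 1")
    n_win = n - (d - 1) * tau
    if n_win < 1:
        raise ValueError(f"series of length {n} too short for order={d}, delay={tau}")
    idx = np.arange(n_win)[:, None] + tau * np.arange(d)[None, :]
    windows = x[idx]
    ranks = np.argsort(windows, axis=1, kind="stable")
    # encode each permutation as a mixed-radix integer
    codes = np.zeros(n_win, dtype=np.int64)
    for j in range(d):
        codes = codes * d + ranks[:, j]
    uniq, counts = np.unique(codes, return_counts=True)
    n_pat = math.factorial(d)
    # map full permutation space to indices
    p = np.zeros(n_pat)
    all_codes = {}
    for i, perm in enumerate(permutations(range(d))):
        code = 0
        for r in perm:
            code = code * d + r
        all_codes[code] = i
    for code, cnt in zip(uniq, counts):
        p[all_codes[int(code)]] = cnt
    return ProbabilityVector(p / n_win)


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy in [0, 1] (base: log d!)."""
    dist = ordinal_distribution(x, order=order, delay=delay)
    return emergence(dist, base_K=math.factorial(int(order)))


def binary_complexity(seq: np.ndarray) -> ComplexityTriple:
    """(E, S, C) of a binary sequence from its 0/1 frequencies (base 2)."""
    seq = np.asarray(seq)
    vals = np.unique(seq)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("sequence must be binary (0/1)")
    p1 = float(np.mean(seq == 1))
    e = emergence(np.array([1.0 - p1, p1]), base_K=2)
    return complexity_triple(e)


def spectral_exponent(x: np.ndarray, fs: float = 1.0) -> float:
    """Spectral scaling exponent beta of 1/f^beta fluctuations.

    Welch periodogram (segments n/8, 50% overlap), OLS slope of
    log power on log frequency over the central band: the lowest two
    and the highest eighth of the positive frequencies are excluded
    (low-frequency leakage and Nyquist rolloff).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 512:
        raise ValueError(f"need at least 512 samples, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant input has no spectrum")
    x = x - x.mean()
    nperseg = max(8, n // 8)
    freqs, power = welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    pos = freqs > 0
    freqs, power = freqs[pos], power[pos]
    hi = int(len(freqs) * 7 // 8)
    band = slice(2, hi)
    f_b, p_b = freqs[band], power[band]
    ok = p_b > 0
    if ok.sum() < 8:
        raise ValueError("too few usable spectral estimates for the fit")
    fit = linregress(np.log(f_b[ok]), np.log(p_b[ok]))
    return -float(fit.slope)


def classify_noise(beta: float, tol: float = 0.5) -> str:
    """Nearest noise archetype: white (0), pink (1), brown (2) or 'other'."""
    name, ref = min(NOISE_ARCHETYPES.items(), key=lambda kv: abs(beta - kv[1]))
    return name if abs(beta - ref) <= tol else "other"
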