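"""Harmonic-baseline disturbance recovery: moisture index, seasonal
harmonic regression, multi-band Euclidean deviation, and the spectral
recovery time.

A per-band harmonic model fitted to the pre-disturbance segment

    y_t = alpha + sum_j gamma_j * sin(2*pi*j*t/f + delta_j) + eps_t

predicts the undisturbed seasonal trajectory; the Euclidean distance
D_t between predictions and observations across bands quantifies
spectral deviation, and the recovery time is how long D_t takes to fall
back below a baseline quantile threshold and stay there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ecoaf.core_io import TimeSeries

__all__ = [
    "HarmonicModel",
    "DeviationSeries",
    "ndmi",
    "fit_harmonic",
    "predict_harmonic",
    "spectral_distance",
    "recovery_time",
]


@dataclass(frozen=True)
class HarmonicModel:
    """Intercept + J phase-shifted sine harmonics at frequency f obs/year.

    amplitudes are nonnegative, phases in [-pi, pi); residual_sd is the
    scale of the fit residuals.
    """

    intercept: float
    amplitudes: np.ndarray
    phases: np.ndarray
    frequency: float
    residual_sd: float
    J: int

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=float)
        ph = np.asarray(self.phases, dtype=float)
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "phases", ph)
        if amp.size != self.J or ph.size != self.J:
            raise ValueError("need one amplitude and phase per harmonic")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be nonnegative")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")


@dataclass
class DeviationSeries:
    """Per-time Euclidean deviation of k bands from their fitted models."""

    times: np.ndarray
    D: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.times.size != self.D.size:
            raise ValueError("times and D must align")
        if np.any(self.D < 0):
            raise ValueError("deviations are nonnegative by construction")


def ndmi(nir, swir1):
    """Normalized difference moisture index (NIR - SWIR1)/(NIR + SWIR1).

    Low for bare soil and thin canopies, high for fully developed ones.
    Accepts scalars or arrays of nonnegative reflectances.
    """
    nir = np.asarray(nir, dtype=float)
    swir1 = np.asarray(swir1, dtype=float)
    if np.any(nir < 0) or np.any(swir1 < 0):
        raise ValueError("reflectances must be nonnegative")
    denom = nir + swir1
    if np.any(denom == 0):
        raise ValueError("NIR + SWIR1 must be nonzero")
    out = (nir - swir1) / denom
    return float(out) if out.ndim == 0 else out


def _design_matrix(times: np.ndarray, f: float, J: int) -> np.ndarray:
    cols = [np.ones_like(times)]
    for j in range(1, J + 1):
        w = 2.0 * np.pi * j * times / f
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    return np.column_stack(cols)


def fit_harmonic(y: np.ndarray, times: np.ndarray, f: float, J: int = 3) -> HarmonicModel:
    """Least-squares harmonic regression via the sin/cos linearization.

    gamma*sin(wt + delta) = a*sin(wt) + b*cos(wt) keeps the fit linear;
    amplitudes/phases are recovered as gamma = hypot(a, b),
    delta = atan2(b, a). Times are in observation units with f
    observations per year (monthly data: t in months, f = 12).
    """
    y = np.asarray(y, dtype=float)
    times = np.asarray(times, dtype=float)
    if y.size != times.size:
        raise ValueError("y and times must align")
    J = int(J)
    if J < 1:
        raise ValueError("need at least one harmonic")
    n_par = 2 * J + 1
    if y.size < n_par + 1:
        raise ValueError(f"need at least {n_par + 1} points to fit {n_par} parameters")
    X = _design_matrix(times, f, J)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    amp = np.empty(J)
    ph = np.empty(J)
    for j in range(J):
        a, b = coef[1 + 2 * j], coef[2 + 2 * j]
        amp[j] = np.hypot(a, b)
        ph[j] = np.arctan2(b, a) if amp[j] > 0 else 0.0
    # fold phases into [-pi, pi)
    ph = np.mod(ph + np.pi, 2.0 * np.pi) - np.pi
    resid = y - X @ coef
    dof = max(y.size - n_par, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return HarmonicModel(
        intercept=float(coef[0]), amplitudes=amp, phases=ph, frequency=float(f), residual_sd=residual_sd, J=J
    )


def predict_harmonic(model: HarmonicModel, times: np.ndarray) -> np.ndarray:
    """Deterministic harmonic prediction at the given times."""
    times = np.asarray(times, dtype=float)
    y = np.full(times.shape, model.intercept)
    for j in range(1, model.J + 1):
        w = 2.0 * np.pi * j * times / model.frequency
        y = y + model.amplitudes[j - 1] * np.sin(w + model.phases[j - 1])
    return y


def spectral_distance(obs: TimeSeries, models: list[HarmonicModel]) -> DeviationSeries:
    """Euclidean deviation D_t = sqrt(sum_i (yhat_it - y_it)^2) over bands."""
    if obs.has_gaps:
        raise ValueError("fill gaps before computing deviations")
    if len(models) != obs.n_vars:
        raise ValueError(f"{len(models)} models for {obs.n_vars} bands")
    sq = np.zeros(obs.n_times)
    for i, model in enumerate(models):
        sq += (predict_harmonic(model, obs.times) - obs.values[i]) ** 2
    return DeviationSeries(times=obs.times.copy(), D=np.sqrt(sq), k=obs.n_vars)


def recovery_time(
    dev: DeviationSeries,
    disturbance_time: float,
    baseline: tuple[float, float],
    q: float = 0.95,
    m: int = 3,
) -> float | None:
    """Spectral recovery duration after a disturbance.

    The threshold is the q-quantile of baseline deviations; recovery is
    the first post-disturbance time at which D stays below the threshold
    for m consecutive observations. Returns that time minus
    ``disturbance_time``, or ``None`` if the deviation never settles.
    """
    t0, t1 = baseline
    if t1 > disturbance_time:
        raise ValueError("baseline must precede the disturbance")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    base = dev.D[(dev.times >= t0) & (dev.times <= t1)]
    if base.size < 10:
        raise ValueError(f"baseline holds only {base.size} observations; need >= 10")
    threshold = float(np.quantile(base, q))
    post = np.where(dev.times > disturbance_time)[0]
    below = dev.D < threshold
    for j, idx in enumerate(post):
        run = post[j : j + m]
        if run.size < m:
            break
        if below[run].all():
            return float(dev.times[idx] - disturbance_time)
    return None
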