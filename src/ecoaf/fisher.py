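"""Sliding-window Fisher information of a phase-space trajectory.

The trajectory form of Fisher information for a phase vector
s = (x_1, ..., x_m) is

    I = (1/T) * integral over one cycle of  s''(t)^2 / s'(t)^4  dt

where s'(t) is the tangential speed sqrt(sum_i (dx_i/dt)^2) and s''(t)
the tangential acceleration (1/s') * sum_i (dx_i/dt)(d^2 x_i/dt^2).
High values indicate regular, low-variability dynamics; drops flag
regime shifts, and re-entry into the pre-disturbance band is read as
recovery.

Derivatives come from the three-point non-uniform stencil (the
interpolating parabola through each interior point and its neighbours),
which is exact for quadratic signals under arbitrary spacing and
reduces to central differences for even spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from ecoaf.core_io import TimeSeries, normalize as _normalize

__all__ = [
    "Derivatives",
    "FisherSeries",
    "phase_derivatives",
    "tangential_speed",
    "tangential_acceleration",
    "fisher_information",
    "dominant_period",
    "detect_recovery",
]


@dataclass
class Derivatives:
    """First/second time derivatives of each variable.

    Endpoints are undefined (NaN): the stencil needs both neighbours.
    ``alpha`` is the per-point spacing ratio (previous gap / following
    gap), 1 everywhere for even sampling.
    """

    d1: np.ndarray  # (m, n)
    d2: np.ndarray  # (m, n)
    alpha: np.ndarray  # (n,)


@dataclass
class FisherSeries:
    """Windowed Fisher information values with window metadata."""

    centers: np.ndarray
    fi: np.ndarray
    window_length: float
    step: float
    eps_speed: float | None
    dropped_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.fi = np.asarray(self.fi, dtype=float)
        self.dropped_fraction = np.asarray(self.dropped_fraction, dtype=float)
        if self.centers.size != self.fi.size:
            raise ValueError("centers and fi must have equal length")
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("window centers must be strictly increasing")
        if np.any(self.fi[np.isfinite(self.fi)] < 0):
            raise ValueError("Fisher information cannot be negative")


def phase_derivatives(ts: TimeSeries) -> Derivatives:
    """Three-point non-uniform finite differences of every variable.

    Exact for quadratics at interior points; endpoint columns are NaN.
    """
    if ts.has_gaps:
        raise ValueError("fill gaps before differentiating")
    t = ts.times
    x = ts.values
    m, n = x.shape
    if n < 3:
        raise ValueError("need at least 3 points for the three-point stencil")
    h_p = t[1:-1] - t[:-2]  # previous spacing
    h_a = t[2:] - t[1:-1]  # following spacing
    alpha = np.full(n, np.nan)
    alpha[1:-1] = h_p / h_a

    d1 = np.full((m, n), np.nan)
    d2 = np.full((m, n), np.nan)
    x_m, x_0, x_p = x[:, :-2], x[:, 1:-1], x[:, 2:]
    # interpolating parabola a*u^2 + b*u + x_0 in local time u = t - t_center
    a = ((x_p - x_0) / h_a + (x_m - x_0) / h_p) / (h_a + h_p)
    b = (x_p - x_0) / h_a - a * h_a
    d1[:, 1:-1] = b
    d2[:, 1:-1] = 2.0 * a
    return Derivatives(d1=d1, d2=d2, alpha=alpha)


def tangential_speed(d: Derivatives) -> np.ndarray:
    """s'(t) = sqrt(sum_i (dx_i/dt)^2), NaN at endpoints."""
    return np.sqrt(np.sum(d.d1**2, axis=0))


def tangential_acceleration(d: Derivatives) -> np.ndarray:
    """s''(t) = (1/s') * sum_i (dx_i/dt)(d^2 x_i/dt^2).

    Undefined (NaN) where the speed vanishes.
    """
    s1 = tangential_speed(d)
    num = np.sum(d.d1 * d.d2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(s1 > 0, num / s1, np.nan)
    return s2


def dominant_period(ts: TimeSeries, var_index: int = 0) -> float:
    """Dominant cycle period of one variable from its periodogram.

    Used as the default window length (one system cycle).
    """
    x = ts.values[var_index]
    dt = float(np.mean(np.diff(ts.times)))
    freqs, power = periodogram(x - x.mean(), fs=1.0 / dt)
    if freqs.size < 2:
        raise ValueError("series too short for a periodogram")
    k = int(np.argmax(power[1:])) + 1
    return 1.0 / freqs[k]


def fisher_information(
    ts: TimeSeries,
    window_length: float | None = None,
    step: float | None = None,
    eps_speed: float | str | None = None,
    normalize: str | None = "auto",
) -> FisherSeries:
    """Windowed trajectory Fisher information.

    Parameters
    ----------
    ts : TimeSeries
        Gap-free trajectory.
    window_length : float, optional
        Window span T in time units (one system cycle). Defaults to the
        dominant periodogram period of the first variable.
    step : float, optional
        Advance between window centers; defaults to one sampling step.
    eps_speed : float or str, optional
        Numerical floor on the tangential speed. Points below the floor
        are excluded from the integral and counted in
        ``dropped_fraction``. Default: 1e-6 times each window's maximum
        speed. A string "qP" (e.g. "q50") floors at the P-th percentile
        of each window's speeds — useful on noise-dominated series,
        where the 1/s'^4 integrand is heavy-tailed and a permissive
        floor lets single slow points dominate whole windows.
    normalize : {"auto", "minmax", None}
        Per-variable min-max normalization before differencing.
        "auto" normalizes only multivariate input (a shared scale is
        needed before mixing units in the speed); None never does.

    Returns
    -------
    FisherSeries
        Windows where every point falls below the speed floor carry
        ``fi = NaN`` (undefined).
    """
    if ts.has_gaps:
        raise ValueError("fill gaps before computing Fisher information")
    if normalize == "auto":
        work = _normalize(ts, "minmax") if ts.n_vars > 1 else ts
    elif normalize == "minmax":
        work = _normalize(ts, "minmax")
    elif normalize is None:
        work = ts
    else:
        raise ValueError(f"unknown normalize option {normalize!r}")

    t = work.times
    dt_mean = float(np.mean(np.diff(t)))
    if window_length is None:
        window_length = dominant_period(work)
    window_length = float(window_length)
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if window_length / dt_mean < 8 - 1e-9:
        raise ValueError(f"window_length={window_length} covers fewer than 8 samples (dt~{dt_mean:g})")
    if step is None:
        step = dt_mean
    step = float(step)
    if step <= 0:
        raise ValueError("step must be positive")

    d = phase_derivatives(work)
    s1 = tangential_speed(d)
    s2 = tangential_acceleration(d)

    interior = slice(1, work.n_times - 1)
    ti, s1i, s2i = t[interior], s1[interior], s2[interior]

    half = window_length / 2.0
    tol = 1e-9 * window_length
    centers, fis, dropped = [], [], []
    c = t[0] + half
    while c <= t[-1] - half + tol:
        sel = (ti >= c - half - tol) & (ti <= c + half + tol)
        n_in = int(sel.sum())
        if n_in >= 2:
            w_t, w_s1, w_s2 = ti[sel], s1i[sel], s2i[sel]
            if eps_speed is None:
                eps = 1e-6 * np.nanmax(w_s1)
            elif isinstance(eps_speed, str):
                if not eps_speed.startswith("q"):
                    raise ValueError(f"eps_speed string must look like 'q50', got {eps_speed!r}")
                eps = float(np.nanquantile(w_s1, float(eps_speed[1:]) / 100.0))
            else:
                eps = float(eps_speed)
            keep = (w_s1 >= eps) & np.isfinite(w_s2)
            n_keep = int(keep.sum())
            if n_keep >= 2:
                integrand = w_s2[keep] ** 2 / w_s1[keep] ** 4
                fi = float(np.trapezoid(integrand, w_t[keep]) / window_length)
            else:
                fi = np.nan
            centers.append(c)
            fis.append(fi)
            dropped.append(1.0 - n_keep / n_in)
        c += step

    if not centers:
        raise ValueError("no complete window fits the series")
    return FisherSeries(
        centers=np.array(centers),
        fi=np.array(fis),
        window_length=window_length,
        step=step,
        eps_speed=eps_speed,
        dropped_fraction=np.array(dropped),
    )


def detect_recovery(
    fs: FisherSeries,
    baseline: tuple[float, float],
    disturbance_time: float,
    k: float = 2.0,
    m: int = 3,
) -> float | None:
    """Time at which Fisher information re-enters its baseline band.

    The band is [mean_b - k*sd_b, +inf) from the baseline windows.
    Returns the first post-disturbance window center from which ``fi``
    stays in the band for ``m`` consecutive windows, or ``None``.
    """
    t0, t1 = baseline
    if t1 > disturbance_time:
        raise ValueError("baseline interval must precede the disturbance time")
    if m < 1:
        raise ValueError("m must be >= 1")
    base_sel = (fs.centers >= t0) & (fs.centers <= t1) & np.isfinite(fs.fi)
    if base_sel.sum() < 5:
        raise ValueError(f"baseline contains only {int(base_sel.sum())} windows; need >= 5")
    mean_b = float(fs.fi[base_sel].mean())
    sd_b = float(fs.fi[base_sel].std(ddof=0))
    lower = mean_b - k * sd_b

    post = np.where(fs.centers > disturbance_time)[0]
    inside = np.isfinite(fs.fi) & (fs.fi >= lower)
    for j, idx in enumerate(post):
        run = post[j : j + m]
        if run.size < m:
            break
        if inside[run].all():
            return float(fs.centers[idx])
    return None
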