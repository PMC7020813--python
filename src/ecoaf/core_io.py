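"""Multivariate time-series container, CSV I/O, preprocessing, and the
autocorrelation characteristic time tau0.

Times are real-valued with an arbitrary origin (monthly satellite series
become t = 0, 1, 2, ... months); no calendar logic anywhere. Missing
values are carried as an explicit boolean mask, never as sentinel
numbers, so derivative-based metrics cannot silently ingest fill values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "TimeSeries",
    "read_timeseries",
    "write_timeseries",
    "interpolate_gaps",
    "normalize",
    "autocorr_tau0",
]


@dataclass
class TimeSeries:
    """A sampled multivariate state trajectory.

    Attributes
    ----------
    times : ndarray, shape (n,)
        Strictly increasing sample times, arbitrary units.
    values : ndarray, shape (m, n)
        One row per state variable.
    names : list of str
        Variable labels, length m.
    mask : ndarray of bool, shape (m, n)
        True where the value is missing (a flagged gap).
    meta : dict
        Free-form provenance.
    """

    times: np.ndarray
    values: np.ndarray
    names: list[str]
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.atleast_2d(np.asarray(self.mask, dtype=bool))
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        m, n = self.values.shape
        if n != self.times.size:
            raise ValueError(f"values has {n} columns but times has {self.times.size} entries")
        if len(self.names) != m:
            raise ValueError(f"{len(self.names)} names for {m} variables")
        if self.mask.shape != (m, n):
            raise ValueError("mask shape must match values")
        if n < 3:
            raise ValueError("need at least 3 time points")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            bad = self.times[1:][dt <= 0][0]
            raise ValueError(f"duplicate or non-monotonic time at t={bad}")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("non-finite value outside the gap mask")

    @property
    def n_vars(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def has_gaps(self) -> bool:
        return bool(self.mask.any())

    def var(self, name: str) -> np.ndarray:
        """Return the value row for a named variable."""
        try:
            i = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown variable {name!r}; have {self.names}") from None
        return self.values[i]

    def copy(self) -> "TimeSeries":
        return TimeSeries(
            self.times.copy(), self.values.copy(), list(self.names), self.mask.copy(), dict(self.meta)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.times})
        for i, name in enumerate(self.names):
            col = self.values[i].copy()
            col[self.mask[i]] = np.nan
            df[name] = col
        return df


def read_timeseries(
    path,
    time_col: str = "t",
    value_cols: Sequence[str] | None = None,
) -> TimeSeries:
    """Read a TimeSeries from a headered CSV file.

    Rows are sorted by time; blank cells become flagged gaps. Duplicate
    times (after sorting) and unknown columns raise ``ValueError``.
    """
    df = pd.read_csv(path)
    if time_col not in df.columns:
        raise ValueError(f"unknown time column {time_col!r} in {path}")
    if value_cols is None:
        value_cols = [c for c in df.columns if c != time_col]
    else:
        missing = [c for c in value_cols if c not in df.columns]
        if missing:
            raise ValueError(f"unknown column(s) {missing} in {path}")
    if not value_cols:
        raise ValueError("no value columns")
    times = pd.to_numeric(df[time_col], errors="raise").to_numpy(dtype=float)
    order = np.argsort(times, kind="stable")
    times = times[order]
    if np.any(np.diff(times) == 0):
        dup = times[1:][np.diff(times) == 0][0]
        raise ValueError(f"duplicate time t={dup}")
    values = np.vstack([pd.to_numeric(df[c], errors="raise").to_numpy(dtype=float)[order] for c in value_cols])
    return TimeSeries(times, values, list(value_cols), meta={"source": str(path)})


def write_timeseries(ts: TimeSeries, path) -> None:
    """Write a TimeSeries as CSV in the same dialect read_timeseries expects."""
    ts.to_frame().to_csv(path, index=False)


def interpolate_gaps(ts: TimeSeries, method: Literal["linear", "ffill"] = "linear") -> TimeSeries:
    """Fill flagged gaps; non-gap values are untouched.

    ``linear`` interpolates in time between the nearest observed
    neighbours and refuses boundary gaps; ``ffill`` propagates the last
    observation forward and refuses leading gaps.
    """
    if method not in ("linear", "ffill"):
        raise ValueError(f"unknown method {method!r}")
    out = ts.copy()
    for i in range(out.n_vars):
        gap = out.mask[i]
        if not gap.any():
            continue
        good = ~gap
        if method == "linear":
            if gap[0] or gap[-1]:
                raise ValueError(
                    f"variable {out.names[i]!r} has a boundary gap; linear interpolation needs interior gaps"
                )
            out.values[i, gap] = np.interp(out.times[gap], out.times[good], out.values[i, good])
        else:
            if gap[0]:
                raise ValueError(f"variable {out.names[i]!r} has a leading gap; cannot forward-fill")
            idx = np.where(good, np.arange(out.n_times), -1)
            idx = np.maximum.accumulate(idx)
            out.values[i] = out.values[i, idx]
        out.mask[i] = False
    return out


def normalize(ts: TimeSeries, mode: Literal["minmax", "zscore"] = "minmax") -> TimeSeries:
    """Rescale each variable: minmax to [0, 1] or zscore to mean 0, sd 1.

    Gap cells are ignored when computing the statistics. A constant
    variable is an error (named in the message) for either mode.
    """
    if mode not in ("minmax", "zscore"):
        raise ValueError(f"unknown mode {mode!r}")
    out = ts.copy()
    for i in range(out.n_vars):
        obs = out.values[i, ~out.mask[i]]
        lo, hi = obs.min(), obs.max()
        if hi == lo:
            raise ValueError(f"variable {out.names[i]!r} is constant; cannot normalize")
        if mode == "minmax":
            out.values[i] = (out.values[i] - lo) / (hi - lo)
        else:
            mu, sd = obs.mean(), obs.std(ddof=0)
            out.values[i] = (out.values[i] - mu) / sd
    return out


def autocorr_tau0(ts: TimeSeries, var: str, max_lag: int) -> float | None:
    """Characteristic memory time: first zero crossing of the sample ACF.

    Uses the biased (divide-by-n, positive-semidefinite) autocorrelation
    estimator with mean removal. The crossing is located by linear
    interpolation between the bracketing integer lags and converted to
    time units with the mean sampling interval. Returns ``None`` if the
    ACF stays positive through ``max_lag``.
    """
    x = ts.var(var)
    if ts.has_gaps:
        raise ValueError("fill gaps before computing autocorrelation")
    n = x.size
    if max_lag >= n:
        raise ValueError(f"max_lag={max_lag} must be < n={n}")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    r = _sm_acf(x, nlags=max_lag, adjusted=False, fft=True)
    dt = float(np.mean(np.diff(ts.times)))
    for k in range(1, max_lag + 1):
        if r[k] <= 0.0:
            if r[k] == 0.0:
                return k * dt
            # linear interpolation between lags k-1 (positive) and k (negative)
            frac = r[k - 1] / (r[k - 1] - r[k])
            return (k - 1 + frac) * dt
    return None
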