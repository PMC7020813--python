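import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoaf.core_io import TimeSeries
from ecoaf.fisher import (
    FisherSeries,
    detect_recovery,
    fisher_information,
    phase_derivatives,
    tangential_acceleration,
    tangential_speed,
)

from helpers import gen_ar1, make_ts


# ---------------------------------------------------------------------------
# independent brute-force oracle: three-point parabola via polyfit, explicit
# loops, hand-rolled trapezoid
# ---------------------------------------------------------------------------

def oracle_fisher_single_window(times, values, eps):
    m, n = values.shape
    d1 = np.full((m, n), np.nan)
    d2 = np.full((m, n), np.nan)
    for i in range(m):
        for j in range(1, n - 1):
            tt = times[j - 1 : j + 2] - times[j]  # local coords for conditioning
            coeffs = np.polyfit(tt, values[i, j - 1 : j + 2], 2)
            d1[i, j] = coeffs[1]
            d2[i, j] = 2.0 * coeffs[0]
    s1 = np.sqrt((d1**2).sum(axis=0))
    s2 = np.empty(n)
    for j in range(n):
        s2[j] = sum(d1[i, j] * d2[i, j] for i in range(m)) / s1[j] if s1[j] > 0 else np.nan
    keep = [j for j in range(1, n - 1) if s1[j] >= eps and np.isfinite(s2[j])]
    integ = [s2[j] ** 2 / s1[j] ** 4 for j in keep]
    total = 0.0
    for a in range(len(keep) - 1):
        dt = times[keep[a + 1]] - times[keep[a]]
        total += 0.5 * (integ[a] + integ[a + 1]) * dt
    T = times[-1] - times[0]
    return total / T


class TestPhaseDerivatives:
    def test_quadratic_even_spacing(self):
        ts = make_ts(np.array([0.0, 1.0, 4.0]), times=[0.0, 1.0, 2.0])
        d = phase_derivatives(ts)
        assert d.d1[0, 1] == pytest.approx(2.0)
        assert d.d2[0, 1] == pytest.approx(2.0)

    def test_linear_any_spacing(self):
        t = np.array([0.0, 0.7, 1.1, 2.9, 3.0])
        ts = make_ts(3.0 * t, times=t)
        d = phase_derivatives(ts)
        np.testing.assert_allclose(d.d1[0, 1:-1], 3.0, atol=1e-12)
        np.testing.assert_allclose(d.d2[0, 1:-1], 0.0, atol=1e-12)

    def test_quadratic_uneven_spacing(self):
        # oracle: parabola through (0,0),(1,1),(3,9) is exactly t^2,
        # so dx/dt=2 and d2x/dt2=2 at t=1
        ts = make_ts(np.array([0.0, 1.0, 9.0]), times=[0.0, 1.0, 3.0])
        d = phase_derivatives(ts)
        assert d.d1[0, 1] == pytest.approx(2.0, abs=1e-12)
        assert d.d2[0, 1] == pytest.approx(2.0, abs=1e-12)
        assert d.alpha[1] == pytest.approx(0.5)

    def test_endpoints_undefined(self):
        ts = make_ts(np.arange(5.0) ** 2)
        d = phase_derivatives(ts)
        assert np.isnan(d.d1[0, 0]) and np.isnan(d.d1[0, -1])
        assert np.isnan(d.d2[0, 0]) and np.isnan(d.d2[0, -1])

    def test_matches_polyfit_oracle_on_random_smooth(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 10, 30))
        x = np.vstack([np.sin(t) + 0.3 * t, np.cos(1.3 * t)])
        d = phase_derivatives(TimeSeries(t, x, ["a", "b"]))
        for i in range(2):
            for j in range(1, 29):
                tt = t[j - 1 : j + 2] - t[j]
                c = np.polyfit(tt, x[i, j - 1 : j + 2], 2)
                assert d.d1[i, j] == pytest.approx(c[1], rel=1e-9, abs=1e-11)
                assert d.d2[i, j] == pytest.approx(2 * c[0], rel=1e-9, abs=1e-11)


class TestSpeedAndAcceleration:
    def test_circle_unit_speed(self):
        t = np.linspace(0, 2 * np.pi, 1001)
        ts = TimeSeries(t, np.vstack([np.cos(t), np.sin(t)]), ["x", "y"])
        d = phase_derivatives(ts)
        s1 = tangential_speed(d)[1:-1]
        assert np.max(np.abs(s1 - 1.0)) < 1e-4

    def test_circle_zero_tangential_acceleration(self):
        t = np.linspace(0, 2 * np.pi, 1001)
        ts = TimeSeries(t, np.vstack([np.cos(t), np.sin(t)]), ["x", "y"])
        d = phase_derivatives(ts)
        s2 = tangential_acceleration(d)[1:-1]
        assert np.max(np.abs(s2)) < 1e-3

    def test_uniform_motion(self):
        ts = make_ts(5.0 * np.arange(10.0))
        d = phase_derivatives(ts)
        np.testing.assert_allclose(tangential_speed(d)[1:-1], 5.0, atol=1e-12)
        np.testing.assert_allclose(tangential_acceleration(d)[1:-1], 0.0, atol=1e-12)

    def test_quadratic_closed_form(self):
        # x = t^2: s' = 2t, s'' = (1/2t)(2t*2) = 2 for t > 0
        t = np.arange(1.0, 11.0)
        ts = make_ts(t**2, times=t)
        d = phase_derivatives(ts)
        np.testing.assert_allclose(tangential_speed(d)[1:-1], 2 * t[1:-1], atol=1e-10)
        np.testing.assert_allclose(tangential_acceleration(d)[1:-1], 2.0, atol=1e-10)

    def test_stationary_point_flagged(self):
        ts = make_ts(np.zeros(5))
        d = phase_derivatives(ts)
        s1 = tangential_speed(d)
        s2 = tangential_acceleration(d)
        assert np.all(s1[1:-1] == 0)
        assert np.all(np.isnan(s2[1:-1]))


class TestFisherInformation:
    def test_circle_near_zero(self):
        t = np.linspace(0, 2 * np.pi, 1001)
        ts = TimeSeries(t, np.vstack([np.cos(t), np.sin(t)]), ["x", "y"])
        fs = fisher_information(ts, window_length=2 * np.pi, normalize=None)
        assert np.all(fs.fi < 1e-6)

    def test_uniform_motion_zero(self):
        ts = make_ts(3.0 * np.arange(100.0))
        fs = fisher_information(ts, window_length=20.0, normalize=None)
        np.testing.assert_allclose(fs.fi, 0.0, atol=1e-20)

    def test_oracle_equivalence_small_n(self):
        rng = np.random.default_rng(11)
        for trial in range(5):
            n = int(rng.integers(20, 51))
            t = np.sort(rng.uniform(0, 10, n))
            x = np.vstack(
                [np.sin(t + rng.uniform(0, 3)) + 0.2 * t, np.cos(0.7 * t) + 0.1 * rng.standard_normal(n)]
            )
            ts = TimeSeries(t, x, ["a", "b"])
            T = t[-1] - t[0]
            fs = fisher_information(ts, window_length=T, eps_speed=1e-300, normalize=None)
            assert fs.fi.size == 1
            expected = oracle_fisher_single_window(t, x, eps=1e-300)
            assert fs.fi[0] == pytest.approx(expected, rel=1e-12)

    def test_ar1_stability_hypothesis(self, ar1_series):
        # derived oracle values (frozen): CV of windowed fi on the
        # stationary AR(1) at seed 42 with a median speed floor, and the
        # ~1/c^2 drop in mean fi after the variance doubles mid-series
        ts = make_ts(ar1_series)
        fs = fisher_information(ts, window_length=12, step=1, eps_speed="q50", normalize=None)
        fi = fs.fi[np.isfinite(fs.fi)]
        cv_stationary = fi.std() / fi.mean()
        assert cv_stationary == pytest.approx(1.623, abs=0.01)

        shifted = gen_ar1(42, sigma_shift_at=300)
        fs2 = fisher_information(make_ts(shifted), window_length=12, step=1, eps_speed="q50", normalize=None)
        pre = np.nanmean(fs2.fi[fs2.centers < 290])
        post = np.nanmean(fs2.fi[fs2.centers > 310])
        assert post < pre / 2  # fi drops when variability rises

    def test_window_too_small_rejected(self):
        ts = make_ts(np.arange(100.0))
        with pytest.raises(ValueError, match="fewer than 8"):
            fisher_information(ts, window_length=4.0)

    def test_dropped_fraction_recorded(self, ar1_series):
        ts = make_ts(ar1_series)
        fs = fisher_information(ts, window_length=12, step=1, eps_speed="q50", normalize=None)
        assert np.all(fs.dropped_fraction >= 0.3)
        assert np.all(fs.dropped_fraction < 1.0)

    def test_all_points_below_floor_undefined(self):
        # constant-plus-single-spike series: huge absolute floor kills windows
        x = np.sin(np.arange(60.0) / 3)
        fs = fisher_information(make_ts(x), window_length=12, eps_speed=1e9, normalize=None)
        assert np.all(np.isnan(fs.fi))
        np.testing.assert_allclose(fs.dropped_fraction, 1.0)


class TestScalingInvariants:
    @given(
        c=st.floats(0.1, 50.0),
        shift=st.floats(-10.0, 10.0),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=20, deadline=None)
    def test_shift_invariance_and_inverse_square_scaling(self, c, shift, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(80.0)
        x = np.vstack(
            [
                np.sin(t / 7 + rng.uniform(0, 3)) + 0.05 * rng.standard_normal(80),
                np.cos(t / 5) + 0.05 * rng.standard_normal(80),
            ]
        )
        base = fisher_information(TimeSeries(t, x, ["a", "b"]), window_length=16, step=4, normalize=None)
        shifted = fisher_information(
            TimeSeries(t, x + shift, ["a", "b"]), window_length=16, step=4, normalize=None
        )
        scaled = fisher_information(
            TimeSeries(t, c * x, ["a", "b"]), window_length=16, step=4, normalize=None
        )
        np.testing.assert_allclose(shifted.fi, base.fi, rtol=1e-9)
        np.testing.assert_allclose(scaled.fi, base.fi / c**2, rtol=1e-9)

    def test_constant_speed_trajectories_zero(self):
        t = np.linspace(0, 4 * np.pi, 2000)
        line = TimeSeries(t, np.vstack([2 * t, -t]), ["a", "b"])
        circle = TimeSeries(t, np.vstack([np.cos(t), np.sin(t)]), ["a", "b"])
        for ts in (line, circle):
            fs = fisher_information(ts, window_length=2 * np.pi, normalize=None)
            assert np.all(fs.fi < 1e-6)


class TestDetectRecovery:
    @staticmethod
    def constructed_series():
        rng = np.random.default_rng(0)
        centers = np.arange(0.0, 30.0)
        fi = 1.0 + 0.05 * rng.standard_normal(30)
        fi[10:16] = 0.2  # collapse at t=10
        fi[16:] = 1.0  # re-entry at t=16, stays
        return FisherSeries(centers, fi, window_length=5, step=1, eps_speed=None, dropped_fraction=np.zeros(30))

    def test_finds_re_entry_exactly(self):
        fs = self.constructed_series()
        assert detect_recovery(fs, (0.0, 9.0), 9.5, k=2.0, m=3) == 16.0

    def test_never_re_enters(self):
        fs = self.constructed_series()
        fi = fs.fi.copy()
        fi[10:] = 0.2
        fs2 = FisherSeries(fs.centers, fi, 5, 1, None, fs.dropped_fraction)
        assert detect_recovery(fs2, (0.0, 9.0), 9.5) is None

    def test_disturbance_before_baseline_end_rejected(self):
        fs = self.constructed_series()
        with pytest.raises(ValueError, match="precede"):
            detect_recovery(fs, (0.0, 9.0), 5.0)

    def test_short_baseline_rejected(self):
        fs = self.constructed_series()
        with pytest.raises(ValueError, match=">= 5"):
            detect_recovery(fs, (0.0, 2.0), 9.5)

    def test_requires_m_consecutive(self):
        fs = self.constructed_series()
        fi = fs.fi.copy()
        fi[17] = 0.2  # blip right after re-entry
        fs2 = FisherSeries(fs.centers, fi, 5, 1, None, fs.dropped_fraction)
        assert detect_recovery(fs2, (0.0, 9.0), 9.5, k=2.0, m=3) == 18.0
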