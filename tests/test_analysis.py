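"""Cross-correlograms, circular statistics, spectra and trajectory shape."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antcpg.analysis import (
    CircularStats,
    amplitude_spectrum,
    circular_mean,
    circular_variance,
    dominant_frequency,
    peak_phase,
    phases_from_trace,
    sliding_crosscorr,
    trajectory_shape,
    working_range,
)
from antcpg.skeleton import tip_trajectories

FS = 50.0


def _shifted_pair(shift_deg, f=1.5625, dur=60.0, rng=None):
    """x and y = x advanced by shift_deg of the oscillation (y leads)."""
    t = np.arange(0, dur, 1 / FS)
    delta = np.deg2rad(shift_deg)
    x = np.sin(2 * np.pi * f * t - delta)
    y = np.sin(2 * np.pi * f * t)
    if rng is not None:
        x = x + 0.05 * rng.standard_normal(len(t))
        y = y + 0.05 * rng.standard_normal(len(t))
    return x, y


class TestSlidingCrosscorr:
    def test_identical_traces_peak_at_zero_everywhere(self, rng):
        x = rng.standard_normal(500).cumsum()  # arbitrary smooth-ish trace
        cg = sliding_crosscorr(x, x, FS)
        zero = np.flatnonzero(cg.lags == 0)[0]
        np.testing.assert_allclose(cg.matrix[zero], 1.0, atol=1e-12)
        assert np.all(cg.matrix <= 1.0 + 1e-12)
        lag, corr = cg.peak()
        assert lag == 0.0 and corr == pytest.approx(1.0)

    def test_known_lead_appears_at_negative_lag(self):
        """y leading x by 20 deg at 1.5625 Hz -> mean-correlogram peak at
        lag = -20/(360*1.5625) s = -35.6 ms."""
        x, y = _shifted_pair(20.0)
        cg = sliding_crosscorr(x, y, FS)
        lag, corr = cg.peak(max_lag=0.5 / 1.5625)  # central peak
        assert lag == pytest.approx(-0.04, abs=0.021)  # nearest grid sample
        assert corr > 0.99
        # sub-sample refinement recovers the exact phase
        assert peak_phase(cg, 1.5625) == pytest.approx(20.0, abs=2.0)

    def test_uncorrelated_noise_has_flat_mean_correlogram(self, rng):
        x = rng.standard_normal(3000)
        y = rng.standard_normal(3000)
        cg = sliding_crosscorr(x, y, FS)
        assert np.max(np.abs(cg.mean)) < 0.1

    def test_swapping_inputs_mirrors_the_lag_axis(self, rng):
        """Exact column-wise relation: corr_yx(-k, c) = corr_xy(k, c - k);
        the per-lag means agree up to the boundary windows the edge-dropping
        rule assigns differently."""
        x, y = _shifted_pair(35.0, rng=rng)
        ab = sliding_crosscorr(x, y, FS)
        ba = sliding_crosscorr(y, x, FS)
        W = 50
        for k in (-30, -7, 0, 13, 42):
            row_ab = np.flatnonzero(np.isclose(ab.lags, k / FS))[0]
            row_ba = np.flatnonzero(np.isclose(ba.lags, -k / FS))[0]
            cols = np.arange(len(ab.centers))
            shifted = cols - k
            ok = (shifted >= 0) & (shifted < len(ab.centers))
            np.testing.assert_allclose(
                ba.matrix[row_ba, cols[ok]], ab.matrix[row_ab, shifted[ok]], atol=1e-12
            )
        np.testing.assert_allclose(ab.mean[::-1], ba.mean, atol=5e-3)

    def test_zero_variance_windows_are_excluded(self):
        x = np.sin(2 * np.pi * 1.5 * np.arange(0, 30, 1 / FS))
        y = x.copy()
        y[200:340] = 0.5  # a flat stretch -> undefined correlations
        cg = sliding_crosscorr(x, y, FS)
        assert np.isnan(cg.matrix).any()
        assert np.all(np.isfinite(cg.mean))

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sliding_crosscorr(np.zeros(100), np.zeros(100), FS, half_window=1.0)

    def test_correlogram_dimensions(self):
        x = np.sin(np.arange(0, 20, 1 / FS))
        cg = sliding_crosscorr(x, x, FS)
        assert cg.lags[0] == -1.0 and cg.lags[-1] == 1.0
        assert cg.matrix.shape == (len(cg.lags), len(cg.centers))
        assert len(cg.mean) == len(cg.lags)


class TestPeakPhase:
    def test_zero_lag_gives_zero_phase(self):
        x, _ = _shifted_pair(0.0)
        cg = sliding_crosscorr(x, x, FS)
        assert peak_phase(cg, 1.5625) == pytest.approx(0.0, abs=0.5)

    @pytest.mark.parametrize("shift", [-90, -60, -20, -5, 5, 20, 45, 90])
    def test_recovers_imposed_shift_within_2_degrees(self, shift):
        x, y = _shifted_pair(shift)
        cg = sliding_crosscorr(x, y, FS)
        assert peak_phase(cg, 1.5625) == pytest.approx(shift, abs=2.0)

    def test_lagging_trace_gives_negative_phase(self):
        y, x = _shifted_pair(20.0)  # now the second trace lags
        cg = sliding_crosscorr(x, y, FS)
        assert peak_phase(cg, 1.5625) == pytest.approx(-20.0, abs=2.0)

    def test_no_interior_peak_raises(self):
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 1.5625 * t)
        y = -x  # anti-phase: the peak sits at the half-period boundary
        cg = sliding_crosscorr(x, y, FS)
        with pytest.raises(ValueError, match="interior"):
            peak_phase(cg, 1.5625)


class TestCircularStatistics:
    def test_identical_phases_have_zero_variance(self):
        assert circular_variance(np.full(10, 0.7)) == pytest.approx(0.0, abs=1e-12)

    def test_balanced_phases_have_unit_variance(self):
        phases = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert circular_variance(phases) == pytest.approx(1.0, abs=1e-12)

    def test_wrapped_normal_variance(self):
        """For a wrapped Normal(0, sigma), 1 - R = 1 - exp(-sigma^2/2)."""
        sigma = np.deg2rad(10.0)
        rng = np.random.default_rng(3)
        phases = rng.normal(0.0, sigma, 10_000)
        expected = 1.0 - np.exp(-(sigma**2) / 2.0)
        assert circular_variance(phases) == pytest.approx(expected, abs=0.005)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(rotation=st.floats(-10, 10), seed=st.integers(0, 1000))
    def test_variance_invariant_under_rotation(self, rotation, seed):
        phases = np.random.default_rng(seed).uniform(0, 2, 64)
        assert circular_variance(phases + rotation) == pytest.approx(
            circular_variance(phases), abs=1e-9
        )

    def test_circular_mean_wraps_correctly(self):
        phases = np.array([0.1, 2 * np.pi - 0.1])
        assert circular_mean(phases) == pytest.approx(0.0, abs=1e-9)

    def test_stats_container(self):
        stats = CircularStats.from_phases(np.full(5, 1.0))
        assert stats.mean_direction == pytest.approx(1.0)
        assert stats.variance == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            circular_variance(np.array([]))


class TestSpectraAndRanges:
    def test_uniform_ramp_percentiles(self):
        wr = working_range(np.linspace(0.0, 100.0, 10_001))
        assert wr.lower == pytest.approx(5.0, abs=0.05)
        assert wr.upper == pytest.approx(95.0, abs=0.05)
        assert wr.width == pytest.approx(90.0, abs=0.1)

    def test_sinusoid_spectrum_peaks_at_bin_8(self):
        t = np.arange(0, 30, 1 / FS)
        mags = amplitude_spectrum(7.0 * np.sin(2 * np.pi * 1.5625 * t), FS)
        assert np.argmax(mags[1:]) + 1 == 8
        assert mags[8] == pytest.approx(7.0, rel=1e-6)

    def test_dominant_frequency_refinement(self):
        t = np.arange(0, 40, 1 / FS)
        x = np.sin(2 * np.pi * 1.43 * t)
        assert dominant_frequency(x, FS) == pytest.approx(1.43, abs=0.01)

    def test_phase_fallback_tracks_oscillation(self):
        t = np.arange(0, 40, 1 / FS)
        x = 5 + 3 * np.sin(2 * np.pi * 1.5 * t)
        ph = phases_from_trace(x, FS)
        rate = np.polyfit(t[200:-200], ph[200:-200], 1)[0]
        assert rate == pytest.approx(2 * np.pi * 1.5, rel=0.02)


class TestTrajectoryShape:
    def _circle_points(self, n=500):
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        u = np.array([1.0, 0.0, 0.0])
        e1 = np.array([0.0, 1.0, 0.0])
        e2 = np.array([0.0, 0.0, 1.0])
        return u * 5.0 + 0.3 * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2))

    def test_line_gives_zero_ratio(self):
        s = np.linspace(-1, 1, 300)
        pts = np.array([5.0, 0.0, 0.0]) + np.outer(s, [0.0, 1.0, 0.5])
        ratio, _ = trajectory_shape(pts)
        assert ratio == pytest.approx(0.0, abs=1e-9)

    def test_circle_gives_unit_ratio(self):
        ratio, _ = trajectory_shape(self._circle_points())
        assert ratio == pytest.approx(1.0, abs=1e-6)

    def test_lissajous_ratio_grows_with_phase_difference(self):
        """Two harmonic joint angles mapped through the kinematics: the
        minor/major ratio is strictly inside (0, 1) at 20 deg and shrinks
        toward 0 as the phase difference vanishes (sine-only drive)."""
        t = np.arange(0, 20, 1 / FS)
        ratios = {}
        for shift in (2.0, 20.0):
            hs = -60.0 + 39.0 * np.sin(2 * np.pi * 1.5625 * t)
            sp = 22.0 + 31.0 * np.sin(2 * np.pi * 1.5625 * t + np.deg2rad(shift))
            angles = np.column_stack(
                [sp, hs, np.zeros_like(t), -hs, -sp]
            )
            tips_l, _ = tip_trajectories(angles)
            ratios[shift], _ = trajectory_shape(tips_l)
        assert 0.0 < ratios[2.0] < ratios[20.0] < 1.0
        assert ratios[2.0] < 0.1

    def test_too_few_or_degenerate_points_rejected(self):
        with pytest.raises(ValueError, match="100"):
            trajectory_shape(np.ones((50, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            trajectory_shape(np.ones((200, 3)))
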