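"""Analysis procedures: sliding cross-correlograms, circular statistics,
working ranges, amplitude spectra and trajectory shape.

The central quantity is the sliding cross-correlogram of the SP joint angle
relative to the HS joint angle: for every window center, the Pearson
correlation of the SP trace shifted by each lag in +/-1 s against the HS
trace within a +/-1 s window.  Averaging over windows gives the mean
cross-correlogram; the lag of its central peak, converted at the dominant
movement frequency, is the inter-joint phase difference.  A *lead* of the
second trace appears as a peak at negative lag, and is reported as a
positive phase in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

__all__ = [
    "Correlogram",
    "CircularStats",
    "WorkingRange",
    "sliding_crosscorr",
    "peak_phase",
    "circular_mean",
    "circular_variance",
    "working_range",
    "amplitude_spectrum",
    "dominant_frequency",
    "trajectory_shape",
    "phases_from_trace",
]


@dataclass
class Correlogram:
    """Sliding cross-correlation matrix.

    ``matrix[k, i]`` is the Pearson correlation at ``lags[k]`` for the
    window centered at ``centers[i]`` (each column is one time window);
    ``mean`` is the per-lag average over all valid windows.  Windows with
    zero variance are recorded as NaN and excluded from the mean.
    """

    lags: np.ndarray  # seconds
    centers: np.ndarray  # seconds
    matrix: np.ndarray  # (n_lags, n_centers)
    mean: np.ndarray  # (n_lags,)

    def peak(self, max_lag: float | None = None) -> tuple[float, float]:
        """(lag_s, correlation) of the maximum of the mean correlogram,
        optionally restricted to |lag| <= max_lag (use half a dominant
        period to pick the central peak of a rhythmic pair)."""
        sel = (
            np.arange(len(self.lags))
            if max_lag is None
            else np.flatnonzero(np.abs(self.lags) <= max_lag)
        )
        k = sel[int(np.nanargmax(self.mean[sel]))]
        return float(self.lags[k]), float(self.mean[k])

    def swapped(self) -> "Correlogram":
        """Lag axis mirrored: the correlogram of the exchanged input traces
        up to the boundary windows the edge-dropping rule reassigns."""
        return Correlogram(
            lags=-self.lags[::-1],
            centers=self.centers.copy(),
            matrix=self.matrix[::-1].copy(),
            mean=self.mean[::-1].copy(),
        )

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.matrix, index=self.lags, columns=self.centers)
        df.index.name = "lag_s"
        df.columns.name = "center_s"
        return df


def sliding_crosscorr(
    x: np.ndarray,
    y: np.ndarray,
    fs: float = 50.0,
    half_window: float = 1.0,
    stride: int = 1,
) -> Correlogram:
    """Sliding-window cross-correlation of ``y`` against ``x``.

    For each window center ``t`` and lag ``tau``, the Pearson correlation of
    ``y(t' + tau)`` against ``x(t')`` over ``t' in [t - half_window,
    t + half_window]``.  A peak at negative lag means ``y`` leads ``x``.
    Edge windows whose lag range would run off the trace are dropped rather
    than zero-padded.

    Parameters
    ----------
    x, y : array-like
        Equal-length, uniformly sampled traces (x is the reference; for the
        antennal convention pass x = HS, y = SP).
    fs : float
        Sampling rate in Hz.
    half_window : float
        Half window size in seconds; the lag grid spans the same +/- range
        at the sample spacing.
    stride : int
        Window-center stride in samples (default 1, i.e. 20 ms at 50 Hz).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d traces")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite samples in input traces")
    W = int(round(half_window * fs))
    if W < 1:
        raise ValueError("half_window too small for the sampling rate")
    wlen = 2 * W + 1
    N = len(x)
    if N < wlen + 2 * W:
        raise ValueError("trace shorter than window plus lag range")

    def normalized_windows(v: np.ndarray) -> np.ndarray:
        win = sliding_window_view(v, wlen)  # (N - wlen + 1, wlen)
        centered = win - win.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(centered, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = centered / norm
        out[norm[:, 0] == 0] = np.nan  # zero-variance windows -> undefined
        return out

    Xn = normalized_windows(x)
    Yn = normalized_windows(y)

    # valid centers: both the x window and every lag-shifted y window exist
    centers_idx = np.arange(2 * W, N - 2 * W, stride)
    lags_idx = np.arange(-W, W + 1)
    xi = centers_idx - W  # x-window start index into the window matrices
    matrix = np.empty((len(lags_idx), len(centers_idx)))
    for row, k in enumerate(lags_idx):
        matrix[row] = np.einsum("ij,ij->i", Xn[xi], Yn[xi + k])
    mean = np.nanmean(matrix, axis=1)
    return Correlogram(
        lags=lags_idx / fs, centers=centers_idx / fs, matrix=matrix, mean=mean
    )


def peak_phase(correlogram: Correlogram, f_dom: float) -> float:
    """Phase lead (degrees) from the central peak of the mean correlogram.

    The search is restricted to lags within half a period of the dominant
    frequency; the peak lag is refined to sub-sample precision by a
    parabolic fit through its neighbors, then converted as
    ``phase = -360 * f_dom * lag``: a peak at negative lag (second trace
    leading) gives a positive phase lead.
    """
    if f_dom <= 0:
        raise ValueError("f_dom must be positive")
    lags, mean = correlogram.lags, correlogram.mean
    half_period = 0.5 / f_dom
    sel = np.flatnonzero(np.abs(lags) <= half_period)
    if sel.size < 3:
        raise ValueError("lag grid too coarse for the dominant frequency")
    k = sel[np.nanargmax(mean[sel])]
    if k == sel[0] or k == sel[-1] or k == 0 or k == len(lags) - 1:
        raise ValueError("no interior peak within half a dominant period")
    y0, y1, y2 = mean[k - 1], mean[k], mean[k + 1]
    denom = y0 - 2.0 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dlag = lags[1] - lags[0]
    lag_peak = lags[k] + delta * dlag
    return float(-360.0 * f_dom * lag_peak)


# ---------------------------------------------------------------------------
# circular statistics


def _resultant(phases: np.ndarray) -> complex:
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("empty phase sample")
    return complex(np.mean(np.exp(1j * phases)))


def circular_mean(phases: np.ndarray) -> float:
    """Mean direction of a sample of phases, in radians (-pi, pi]."""
    return float(np.angle(_resultant(phases)))


def circular_variance(phases: np.ndarray) -> float:
    """Circular variance ``1 - R`` with R the mean resultant length.

    0 for perfectly concentrated phases, 1 for a balanced (e.g. uniform)
    distribution.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size < 2:
        raise ValueError("need at least 2 phase samples")
    return float(1.0 - abs(_resultant(phases)))


@dataclass(frozen=True)
class CircularStats:
    """Summary circular statistics of a phase sample."""

    mean_direction: float
    resultant_length: float

    @property
    def variance(self) -> float:
        return 1.0 - self.resultant_length

    @classmethod
    def from_phases(cls, phases: np.ndarray) -> "CircularStats":
        z = _resultant(np.asarray(phases, dtype=float))
        return cls(mean_direction=float(np.angle(z)), resultant_length=abs(z))


# ---------------------------------------------------------------------------
# working ranges and spectra


@dataclass(frozen=True)
class WorkingRange:
    """5th-to-95th percentile span of a joint-angle time course (degrees)."""

    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower


def working_range(angles: np.ndarray) -> WorkingRange:
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0 or not np.all(np.isfinite(angles)):
        raise ValueError("angles must be a non-empty finite array")
    lo, hi = np.percentile(angles, [5.0, 95.0])
    return WorkingRange(lower=float(lo), upper=float(hi))


def amplitude_spectrum(
    trace: np.ndarray, fs: float = 50.0, T: float = 5.12, L: int | None = None
) -> np.ndarray:
    """Per-harmonic magnitudes ``|z_n| = sqrt(a_n^2+b_n^2)`` of a trace.

    The trace is cut into consecutive non-overlapping ``fs*T`` windows
    (256 samples by default) and the unnormalized Fourier magnitudes are
    averaged across windows; ``out[0]`` holds the absolute mean.  ``L``
    truncates the returned harmonic count.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("non-finite samples")
    N = int(round(fs * T))
    if abs(fs * T - N) > 1e-9:
        raise ValueError("fs*T must be an integer number of samples")
    n_win = len(trace) // N
    if n_win < 1:
        raise ValueError(f"trace shorter than the fs*T={N} sample window")
    segs = trace[: n_win * N].reshape(n_win, N)
    X = np.fft.rfft(segs, axis=1) / N
    mags = 2.0 * np.abs(X)
    mags[:, 0] /= 2.0
    out = mags.mean(axis=0)
    return out if L is None else out[: L + 1]


def dominant_frequency(trace: np.ndarray, fs: float = 50.0) -> float:
    """Dominant frequency (Hz) of a trace from its full-length periodogram,
    refined by parabolic interpolation around the spectral peak."""
    trace = np.asarray(trace, dtype=float)
    f, p = sps.periodogram(trace - trace.mean(), fs=fs)
    if len(p) < 4:
        raise ValueError("trace too short for a spectral estimate")
    k = int(np.argmax(p[1:])) + 1
    if 1 <= k < len(p) - 1:
        y0, y1, y2 = p[k - 1], p[k], p[k + 1]
        denom = y0 - 2.0 * y1 + y2
        delta = 0.0 if denom == 0 else float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    else:
        delta = 0.0
    return float(f[k] + delta * (f[1] - f[0]))


# ---------------------------------------------------------------------------
# trajectory shape


def trajectory_shape(points: np.ndarray) -> tuple[float, float]:
    """Shape of a tip trajectory: (minor/major axis ratio, orientation).

    Points are projected onto the plane orthogonal to the mean antennal
    direction (the normalized centroid direction); the ratio is
    ``sqrt(lambda_min / lambda_max)`` of the 2-D covariance eigenvalues,
    0 for collinear points and 1 for a circle.  The orientation is the
    angle (radians) of the major axis within the projection plane.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must have shape (N, 3)")
    if len(points) < 100:
        raise ValueError("need at least 100 trajectory points")
    centroid = points.mean(axis=0)
    norm = np.linalg.norm(centroid)
    if norm == 0:
        raise ValueError("degenerate trajectory (centroid at origin)")
    u = centroid / norm
    # orthonormal in-plane basis
    helper = np.array([0.0, 0.0, 1.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    rel = points - centroid
    proj = np.column_stack([rel @ e1, rel @ e2])
    cov = np.cov(proj.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 1e-18:
        raise ValueError("degenerate trajectory (all points identical)")
    ratio = float(np.sqrt(max(evals[0], 0.0) / evals[-1]))
    major = evecs[:, -1]
    orientation = float(np.arctan2(major[1], major[0]))
    return ratio, orientation


# ---------------------------------------------------------------------------
# instantaneous phase from recorded traces (fallback for external data)


def phases_from_trace(
    trace: np.ndarray, fs: float = 50.0, f_dom: float | None = None
) -> np.ndarray:
    """Instantaneous phase (radians, unwrapped) of the dominant rhythm.

    Inside a simulation the oscillator phases theta are available directly
    and should be preferred; this trace-based fallback demodulates the
    dominant harmonic by band-limiting the analytic signal to
    ``[0.5, 1.5] * f_dom``.
    """
    trace = np.asarray(trace, dtype=float)
    if f_dom is None:
        f_dom = dominant_frequency(trace, fs)
    X = np.fft.fft(trace - trace.mean())
    f = np.fft.fftfreq(len(trace), d=1.0 / fs)
    band = (f >= 0.5 * f_dom) & (f <= 1.5 * f_dom)
    analytic = np.fft.ifft(np.where(band, 2.0 * X, 0.0))
    return np.unwrap(np.angle(analytic))
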