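"""Pattern-formation networks: truncated Fourier descriptions of joint-angle
waveforms.

The rhythm-generating layer of the CPG outputs an amplitude, offset and a
monotonically increasing phase per joint.  The pattern-formation layer turns
that phase into the temporal fine structure of the joint movement through a
truncated Fourier series

    F(theta) = M * sum_{n=1..L} [ a_n cos(n*Psi) + b_n sin(n*Psi) ],
    Psi = theta / n_dom,

fitted to a ``T = 5.12 s`` window of a joint-angle recording sampled at 50 Hz
(256 points, harmonic spacing ``1/T = 0.1953 Hz``; the dominant antennal
component sits in bin ``n_dom = 8``, i.e. 1.5625 Hz).  ``Psi`` divides the
oscillator phase by the dominant harmonic index so that the dominant component
of ``F`` completes exactly one period per oscillator cycle and the full
pattern repeats every ``n_dom`` cycles (~5 s at 1.45-1.56 Hz).  ``M``
normalizes the peak of ``F`` to 1, which makes the oscillator amplitude ``mu``
the half-range of the joint excursion in degrees.

The module also provides the three pattern variants used in the experiments
(single-trial ``Mc``, population-mean ``Mm``, mean-plus-variability ``Mmsd``)
and the triangular / augmented-triangular test waveforms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FourierPattern",
    "PatternVariant",
    "fit_fourier",
    "reconstruct",
    "reconstruction_rmse",
    "make_triangular",
    "make_augmented_triangular",
    "sine_pattern",
    "sample_variant",
    "read_coefficients",
    "write_coefficients",
]

#: default analysis-window length in seconds (50 Hz * 5.12 s = 256 samples)
DEFAULT_T = 5.12
#: default number of retained harmonics
DEFAULT_L = 16
#: grid density used for peak normalization and symmetry checks
_NORM_GRID = 4096


@dataclass(frozen=True)
class FourierPattern:
    """Truncated Fourier description of a periodic joint-angle waveform.

    Parameters
    ----------
    a, b : ndarray, shape (L+1,)
        Raw cosine/sine coefficients in degrees; ``a[0]`` holds the fitted DC
        term (the mean joint angle of the source window) and ``b[0]`` must be
        zero.  The DC term is excluded from the normalized pattern: the mean
        position of a joint is carried by the oscillator offset state ``c``,
        not by ``F``.
    T : float
        Window length of the source fit in seconds; harmonic ``n`` maps to
        frequency ``n / T`` Hz.
    n_dom : int, optional
        Dominant harmonic index.  Defaults to ``argmax_n |z_n|`` for
        ``n >= 1`` with ``|z_n| = sqrt(a_n^2 + b_n^2)``.
    """

    a: np.ndarray
    b: np.ndarray
    T: float = DEFAULT_T
    n_dom: int | None = None
    M: float = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("a and b must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("non-finite Fourier coefficients")
        if abs(b[0]) > 1e-12:
            raise ValueError("b_0 must be zero")
        if self.T <= 0:
            raise ValueError("window length T must be positive")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        mags = np.hypot(a[1:], b[1:]) if len(a) > 1 else np.zeros(0)
        degenerate = mags.size == 0 or not np.any(mags > 0)
        n_dom = self.n_dom
        if n_dom is None:
            # all-zero harmonics: F == 0 (offset-only drive), M = 0
            n_dom = 1 if degenerate else int(np.argmax(mags)) + 1
        elif not (1 <= n_dom <= max(len(a) - 1, 1)):
            raise ValueError("n_dom outside coefficient range")
        object.__setattr__(self, "n_dom", n_dom)
        if self.M is None:
            object.__setattr__(self, "M", 0.0 if degenerate else 1.0 / self._raw_peak())

    # -- basic properties ---------------------------------------------------

    @property
    def L(self) -> int:
        """Highest harmonic index carried by the pattern."""
        return len(self.a) - 1

    @property
    def f1(self) -> float:
        """Fundamental frequency of the analysis window in Hz."""
        return 1.0 / self.T

    @property
    def dc(self) -> float:
        """Fitted mean of the source window in degrees (not part of F)."""
        return float(self.a[0])

    @property
    def magnitudes(self) -> np.ndarray:
        """Per-harmonic magnitudes ``|z_n|`` (raw scale), n = 0..L."""
        out = np.hypot(self.a, self.b)
        out[0] = abs(self.a[0])
        return out

    @property
    def normalized(self) -> bool:
        return self.M is not None

    def _eval_raw(self, psi: np.ndarray | float) -> np.ndarray | float:
        psi = np.asarray(psi, dtype=float)
        n = np.arange(1, self.L + 1)
        ang = np.multiply.outer(psi, n)
        out = np.cos(ang) @ self.a[1:] + np.sin(ang) @ self.b[1:]
        return out if out.ndim else float(out)

    def _raw_peak(self) -> float:
        # grid search plus bounded refinement: the pattern is band-limited,
        # so the true extremum sits within one grid cell of the grid argmax
        from scipy.optimize import minimize_scalar

        psi = np.linspace(0.0, 2.0 * np.pi, _NORM_GRID, endpoint=False)
        vals = np.abs(self._eval_raw(psi))
        k = int(np.argmax(vals))
        if vals[k] <= 0:
            raise ValueError("cannot normalize an all-zero pattern")
        h = 2.0 * np.pi / _NORM_GRID
        res = minimize_scalar(
            lambda p: -abs(self._eval_raw(p)),
            bounds=(psi[k] - h, psi[k] + h),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return float(max(vals[k], -res.fun))

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, theta: np.ndarray | float) -> np.ndarray | float:
        """Normalized pattern value ``F(theta)`` in [-1, 1].

        ``theta`` is the oscillator phase in radians (unwrapped or wrapped;
        F is ``2*pi*n_dom``-periodic in theta).
        """
        if not self.normalized:
            raise ValueError("pattern is not normalized (scaling M missing)")
        psi = np.asarray(theta, dtype=float) / self.n_dom
        out = self.M * self._eval_raw(psi)
        return out

    __call__ = evaluate

    def evaluate_psi(self, psi: np.ndarray | float) -> np.ndarray | float:
        """Normalized pattern as a function of the pattern phase ``Psi``."""
        if not self.normalized:
            raise ValueError("pattern is not normalized (scaling M missing)")
        return self.M * self._eval_raw(psi)

    # -- transformations ----------------------------------------------------

    def align_dominant(self) -> "FourierPattern":
        """Rotate the pattern phase so the dominant harmonic is a pure sine.

        Writing harmonic ``n`` as ``m_n sin(n*Psi + psi_n)``, the rotation
        ``Psi -> Psi - psi_dom/n_dom`` zeroes the dominant phase, so that
        ``F(theta) ~ sin(theta)`` to leading order.  Patterns fitted from
        recorded data must be aligned before being installed in the CPG:
        the inter-joint phase lead is then set exclusively by the oscillator
        phase biases ``phi_ij`` instead of being double-counted from the
        phases already present in the recording.
        """
        nd = self.n_dom
        delta = np.arctan2(self.a[nd], self.b[nd]) / nd
        n = np.arange(len(self.a))
        mag = np.hypot(self.a, self.b)
        psi_n = np.arctan2(self.a, self.b) - n * delta
        a_new = mag * np.sin(psi_n)
        b_new = mag * np.cos(psi_n)
        a_new[0] = self.a[0]
        b_new[0] = 0.0
        return FourierPattern(a=a_new, b=b_new, T=self.T, n_dom=nd)

    def with_magnitudes(self, magnitudes: np.ndarray) -> "FourierPattern":
        """Return a pattern with harmonic magnitudes replaced, phases kept."""
        magnitudes = np.asarray(magnitudes, dtype=float)
        if magnitudes.shape != self.a.shape:
            raise ValueError("magnitude array must match coefficient length")
        if np.any(magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")
        psi_n = np.arctan2(self.a, self.b)
        a_new = magnitudes * np.sin(psi_n)
        b_new = magnitudes * np.cos(psi_n)
        a_new[0] = self.a[0]
        b_new[0] = 0.0
        return FourierPattern(a=a_new, b=b_new, T=self.T)


# ---------------------------------------------------------------------------
# fitting and reconstruction


def _window_samples(fs: float, T: float) -> int:
    n = fs * T
    N = int(round(n))
    if abs(n - N) > 1e-9 or N < 2:
        raise ValueError(f"fs*T must be a positive integer, got {n!r}")
    return N


def fit_fourier(
    series: np.ndarray,
    fs: float = 50.0,
    T: float = DEFAULT_T,
    L: int = DEFAULT_L,
) -> FourierPattern:
    """Fit the first ``L`` Fourier harmonics of a joint-angle window.

    Parameters
    ----------
    series : array-like
        Uniformly sampled joint angles in degrees.  Only the first
        ``fs*T`` samples are used.
    fs : float
        Sampling rate in Hz (50 Hz for the motion-capture convention).
    T : float
        Window length in seconds.  ``fs*T`` must be an integer; the default
        50 Hz x 5.12 s gives a 256-sample window.
    L : int
        Number of retained harmonics (default 16).

    Returns
    -------
    FourierPattern
        Normalized pattern; the window mean is stored in ``a[0]`` and the
        raw (unnormalized) coefficients are retained for reconstruction.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite samples")
    N = _window_samples(fs, T)
    if len(series) < N:
        raise ValueError(f"series shorter than the fs*T={N} sample window")
    if not (1 <= L <= N // 2):
        raise ValueError("L must lie between 1 and fs*T/2")
    X = np.fft.rfft(series[:N]) / N
    a = np.zeros(L + 1)
    b = np.zeros(L + 1)
    a[0] = X[0].real
    a[1:] = 2.0 * X[1 : L + 1].real
    b[1:] = -2.0 * X[1 : L + 1].imag
    return FourierPattern(a=a, b=b, T=T)


def reconstruct(pattern: FourierPattern, fs: float = 50.0, T: float | None = None) -> np.ndarray:
    """Inverse evaluation of the raw (unnormalized) fit on the uniform grid.

    Returns the ``fs*T``-sample time course (degrees), including the fitted
    DC term, i.e. the band-limited approximation of the original window.
    """
    T = pattern.T if T is None else T
    N = _window_samples(fs, T)
    psi = 2.0 * np.pi * np.arange(N) / N
    return pattern.dc + np.asarray(pattern._eval_raw(psi))


def reconstruction_rmse(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """RMSE between an angle window and its reconstruction, in degrees."""
    original = np.asarray(original, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if original.shape != reconstructed.shape:
        raise ValueError("length mismatch between original and reconstruction")
    return float(np.sqrt(np.mean((original - reconstructed) ** 2)))


# ---------------------------------------------------------------------------
# canonical test waveforms


def make_triangular(
    n_components: int = 4, n_dom: int = 8, T: float = DEFAULT_T
) -> FourierPattern:
    """Symmetric triangular waveform (sine terms only).

    Harmonics sit at odd multiples of ``n_dom`` with the triangle-wave
    weights ``(-1)^k / (2k+1)^2``; in time the components are the odd
    harmonics of the dominant joint frequency.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    Lmax = (2 * n_components - 1) * n_dom
    a = np.zeros(Lmax + 1)
    b = np.zeros(Lmax + 1)
    for k in range(n_components):
        b[(2 * k + 1) * n_dom] = (-1.0) ** k / (2 * k + 1) ** 2
    return FourierPattern(a=a, b=b, T=T, n_dom=n_dom)


def make_augmented_triangular(
    n_components: int = 4, n_dom: int = 8, T: float = DEFAULT_T
) -> FourierPattern:
    """Triangular waveform augmented with equal-magnitude cosine terms.

    The same odd harmonics appear as both sine and cosine components, giving
    the waveform a second, non-trivial phase in its phase spectrum: the
    rise and fall of each half-wave become asymmetric (time-reversal symmetry
    is broken) while the frequency content matches :func:`make_triangular`.
    """
    tri = make_triangular(n_components=n_components, n_dom=n_dom, T=T)
    a = tri.b.copy()
    a[0] = 0.0
    return FourierPattern(a=a, b=tri.b.copy(), T=T, n_dom=n_dom)


def sine_pattern(n_dom: int = 8, T: float = DEFAULT_T) -> FourierPattern:
    """Pure sinusoidal pattern, ``F(theta) = sin(theta)``.

    Used for the neck oscillator, whose small-amplitude yaw rhythm is modeled
    as a plain sinusoid.
    """
    a = np.zeros(n_dom + 1)
    b = np.zeros(n_dom + 1)
    b[n_dom] = 1.0
    return FourierPattern(a=a, b=b, T=T, n_dom=n_dom)


# ---------------------------------------------------------------------------
# pattern variants


@dataclass(frozen=True)
class PatternVariant:
    """One of the three CPG patterning networks for a given joint.

    ``Mc`` uses a single representative trial's spectrum unchanged, ``Mm``
    the population-mean spectrum, and ``Mmsd`` the mean spectrum with
    per-harmonic magnitude variability of one standard deviation.  ``Mmsd``
    perturbs component magnitudes only; harmonic phases are preserved.
    """

    kind: str
    base: FourierPattern
    magnitude_sd: np.ndarray | None = None

    _KINDS = ("Mc", "Mm", "Mmsd")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if self.magnitude_sd is not None:
            sd = np.asarray(self.magnitude_sd, dtype=float)
            if sd.shape != self.base.a.shape:
                raise ValueError("magnitude_sd must match coefficient length")
            if np.any(sd < 0):
                raise ValueError("magnitude_sd must be non-negative")
            object.__setattr__(self, "magnitude_sd", sd)
        elif self.kind == "Mmsd":
            raise ValueError("Mmsd variant requires per-component magnitude SDs")


def sample_variant(
    variant: PatternVariant, rng: np.random.Generator | None = None
) -> FourierPattern:
    """Draw a concrete pattern from a variant.

    ``Mc`` and ``Mm`` return the base pattern unchanged (they are
    deterministic); ``Mmsd`` perturbs each harmonic magnitude by
    ``Normal(0, sd_n)``, truncates at zero, keeps the phases, and
    re-normalizes.
    """
    if variant.kind in ("Mc", "Mm"):
        return variant.base
    if rng is None:
        raise ValueError("Mmsd sampling requires a random generator")
    mags = variant.base.magnitudes.copy()
    sd = variant.magnitude_sd
    perturbed = np.maximum(mags + rng.normal(0.0, 1.0, size=mags.shape) * sd, 0.0)
    perturbed[0] = mags[0]
    return variant.base.with_magnitudes(perturbed)


# ---------------------------------------------------------------------------
# coefficient file I/O (CSV with columns n, a_n, b_n; degrees, b_0 = 0)


def write_coefficients(pattern: FourierPattern, path) -> None:
    """Write raw coefficients to CSV (columns ``n``, ``a_n``, ``b_n``)."""
    df = pd.DataFrame(
        {"n": np.arange(len(pattern.a)), "a_n": pattern.a, "b_n": pattern.b}
    )
    df.to_csv(path, index=False)


def read_coefficients(path, T: float = DEFAULT_T) -> FourierPattern:
    """Read a coefficient CSV written by :func:`write_coefficients`."""
    df = pd.read_csv(path)
    for col in ("n", "a_n", "b_n"):
        if col not in df.columns:
            raise ValueError(f"coefficient file missing column {col!r}")
    df = df.sort_values("n")
    n = df["n"].to_numpy()
    if not np.array_equal(n, np.arange(len(n))):
        raise ValueError("coefficient file must list n = 0..L contiguously")
    return FourierPattern(
        a=df["a_n"].to_numpy(float), b=df["b_n"].to_numpy(float), T=T
    )
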