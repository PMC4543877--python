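"""Surrogate antennal joint-angle recordings.

The motion-capture recordings that the pattern-formation networks were
designed from (10 trials, 5 animals, 50 Hz) are not published; this module
generates surrogates with the documented statistical structure so that
pattern fitting, the Mm/Mmsd variants and all analyses can run without any
external data:

* quasi-rhythmic HS and SP traces with a dominant spectral component near
  1.56 Hz (per-animal dominant frequencies in the observed 1.36-1.95 Hz
  range),
* Table-style amplitude/offset statistics (HS: 39 deg about -60 deg,
  SP: 31 deg about +22 deg intact) with per-half-cycle upper/lower
  amplitude jitter and per-cycle frequency jitter,
* a fixed SP-vs-HS phase lead (20 deg by default) shared through common
  cycle timing, while amplitude jitter is drawn independently per joint.

Harmonic magnitudes decay as ``c/|n - n_dom| + baseline`` away from the
dominant bin — a parameterized stand-in for the measured spectra, not a fit
to any individual animal.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .pattern_formation import (
    DEFAULT_L,
    DEFAULT_T,
    FourierPattern,
    PatternVariant,
    fit_fourier,
)
from . import analysis

__all__ = [
    "JointStatistics",
    "SyntheticTrialSpec",
    "SyntheticTrial",
    "Population",
    "generate_trial",
    "generate_population",
    "default_mc_pattern",
    "default_variants",
    "DEFAULT_DATA_SEED",
]

#: seed of the packaged default dataset (representative trial + population)
DEFAULT_DATA_SEED = 20150821

_DEG = np.pi / 180.0


@dataclass(frozen=True)
class JointStatistics:
    """Mean offset/amplitude (degrees) and upper/lower bound SDs of one
    joint's angle time course."""

    offset: float
    amplitude: float
    upper_sd: float
    lower_sd: float

    def __post_init__(self) -> None:
        if self.amplitude < 0 or min(self.upper_sd, self.lower_sd) < 0:
            raise ValueError("amplitude and bound SDs must be non-negative")


#: intact-condition joint statistics
HS_INTACT = JointStatistics(offset=-60.0, amplitude=39.0, upper_sd=8.0, lower_sd=9.0)
SP_INTACT = JointStatistics(offset=22.0, amplitude=31.0, upper_sd=9.0, lower_sd=15.0)

#: observed range of per-animal dominant frequencies (Hz)
F_DOM_RANGE = (1.36, 1.95)
#: center/SD of the per-animal dominant-frequency draws: the population
#: spectrum peaks near the 1.56 Hz analysis bin while individual animals
#: spread over the observed range
F_DOM_CENTER = 1.5625
F_DOM_SD = 0.12


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Parameters of one surrogate trial.

    ``f_dom`` defaults to the 1.5625 Hz analysis bin (bin 8 of the 5.12 s
    window); ``f_cycle_sd`` is the SD of the per-cycle frequency draws and
    ``phase_lead_deg`` the imposed lead of the SP trace over the HS trace,
    measured on the dominant component.
    """

    duration: float = 60.0
    fs: float = 50.0
    hs: JointStatistics = HS_INTACT
    sp: JointStatistics = SP_INTACT
    f_dom: float = 1.5625
    f_cycle_sd: float = 0.05
    phase_lead_deg: float = 20.0
    n_dom: int = 8
    n_harmonics: int = DEFAULT_L
    decay: float = 0.15
    baseline: float = 0.02
    T: float = DEFAULT_T
    #: optional per-animal multipliers on the harmonic magnitudes
    harmonic_gain: tuple | None = None

    def __post_init__(self) -> None:
        if not F_DOM_RANGE[0] <= self.f_dom <= F_DOM_RANGE[1]:
            raise ValueError(
                f"f_dom must lie within the observed range {F_DOM_RANGE}"
            )
        if self.duration < 2 * self.T:
            raise ValueError("duration must cover at least two analysis windows")
        if self.f_cycle_sd < 0:
            raise ValueError("f_cycle_sd must be non-negative")
        if not (1 <= self.n_dom <= self.n_harmonics):
            raise ValueError("n_dom must lie within the harmonic range")


@dataclass
class SyntheticTrial:
    """One generated trial: time (s) and HS/SP joint angles (degrees)."""

    time: np.ndarray
    hs: np.ndarray
    sp: np.ndarray
    spec: SyntheticTrialSpec
    seed: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "hs_deg": self.hs, "sp_deg": self.sp}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _harmonic_profile(spec: SyntheticTrialSpec) -> np.ndarray:
    """Magnitude profile m_n, n = 0..n_harmonics; peak 1 at n_dom."""
    n = np.arange(spec.n_harmonics + 1, dtype=float)
    with np.errstate(divide="ignore"):
        m = spec.decay / np.abs(n - spec.n_dom) + spec.baseline
    m[spec.n_dom] = 1.0
    m[0] = 0.0
    if spec.harmonic_gain is not None:
        gain = np.asarray(spec.harmonic_gain, dtype=float)
        if gain.shape != m.shape:
            raise ValueError("harmonic_gain must have length n_harmonics+1")
        m = m * gain
    return m


def _dominant_phase(spec: SyntheticTrialSpec, rng: np.random.Generator) -> np.ndarray:
    """Unwrapped dominant-component phase on the sample grid, built from
    piecewise-constant per-cycle frequency draws."""
    n_samples = int(round(spec.duration * spec.fs))
    t = np.arange(n_samples) / spec.fs
    # enough cycles to cover the duration even with slow draws
    n_cycles = int(np.ceil(spec.duration * spec.f_dom * 2)) + 4
    freqs = spec.f_dom + spec.f_cycle_sd * rng.standard_normal(n_cycles)
    freqs = np.maximum(freqs, 0.2 * spec.f_dom)  # guard absurd draws
    bounds = np.concatenate([[0.0], np.cumsum(1.0 / freqs)])
    phases = 2.0 * np.pi * np.arange(n_cycles + 1)
    return t, np.interp(t, bounds, phases)


def _waveform(
    psi: np.ndarray, mags: np.ndarray, phases: np.ndarray
) -> np.ndarray:
    n = np.arange(len(mags), dtype=float)
    ang = np.multiply.outer(psi, n) + phases[None, :]
    w = np.sin(ang) @ mags
    # normalize the peak over one pattern period on a fine grid
    grid = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    gang = np.multiply.outer(grid, n) + phases[None, :]
    peak = np.max(np.abs(np.sin(gang) @ mags))
    return w / peak


def _envelope(
    w: np.ndarray, stats: JointStatistics, rng: np.random.Generator
) -> np.ndarray:
    """Per-half-cycle amplitude draws: segments of constant amplitude
    separated by the zero crossings of the waveform (so the angle trace is
    continuous)."""
    sign = np.sign(w)
    sign[sign == 0] = 1.0
    change = np.flatnonzero(np.diff(sign) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(w)]])
    amp = np.empty_like(w)
    for s, e in zip(starts, ends):
        sd = stats.upper_sd if w[s] >= 0 else stats.lower_sd
        amp[s:e] = max(0.0, stats.amplitude + sd * rng.standard_normal())
    return amp


def generate_trial(
    spec: SyntheticTrialSpec | None = None, seed: int | None = None
) -> SyntheticTrial:
    """Generate one surrogate trial (deterministic per seed).

    HS and SP share the per-cycle timing (common dominant phase), so the
    imposed SP lead is well defined; their harmonic phases and amplitude
    jitter are drawn independently per joint.
    """
    if spec is None:
        spec = SyntheticTrialSpec()
    rng = np.random.default_rng(seed)
    mags = _harmonic_profile(spec)

    # per-joint harmonic phases; the dominant component is a pure sine of
    # the shared cycle phase so the lead is carried by a clean offset
    def joint_phases() -> np.ndarray:
        ph = rng.uniform(0.0, 2.0 * np.pi, size=len(mags))
        ph[spec.n_dom] = 0.0
        return ph

    ph_hs = joint_phases()
    ph_sp = joint_phases()

    t, theta_dom = _dominant_phase(spec, rng)
    psi_hs = theta_dom / spec.n_dom
    psi_sp = psi_hs + spec.phase_lead_deg * _DEG / spec.n_dom

    w_hs = _waveform(psi_hs, mags, ph_hs)
    w_sp = _waveform(psi_sp, mags, ph_sp)
    hs = spec.hs.offset + _envelope(w_hs, spec.hs, rng) * w_hs
    sp = spec.sp.offset + _envelope(w_sp, spec.sp, rng) * w_sp
    return SyntheticTrial(time=t, hs=hs, sp=sp, spec=spec, seed=seed)


# ---------------------------------------------------------------------------
# population generation


@dataclass
class Population:
    """A set of surrogate trials plus per-harmonic spectra summaries.

    ``spectra[joint]`` has shape (n_trials, L+1) (unnormalized magnitudes,
    degrees); ``summary[joint]`` maps ``mean``/``sd``/``min``/``max`` to
    per-harmonic arrays, the inputs of the Mm and Mmsd variants.
    """

    trials: list[SyntheticTrial]
    spectra: dict[str, np.ndarray]
    summary: dict[str, dict[str, np.ndarray]]
    animal_f_dom: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "animal_f_dom_hz": self.animal_f_dom.tolist(),
            "summary": {
                joint: {k: v.tolist() for k, v in stats.items()}
                for joint, stats in self.summary.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def generate_population(
    n_animals: int = 5,
    trials_per_animal: int = 2,
    seed: int | None = None,
    base: SyntheticTrialSpec | None = None,
) -> Population:
    """Generate the surrogate population (default 5 animals x 2 trials).

    Per-animal dominant frequencies are a stratified sample of a normal
    distribution centered on the 1.56 Hz population peak, truncated to the
    observed 1.36-1.95 Hz range: with only a handful of animals, quantile
    spacing keeps the surrogate population representative of that
    distribution for any seed (the population-mean spectrum peaks at the
    dominant bin by construction).  Harmonic-magnitude multipliers are drawn
    once per animal, per-trial jitter independently.
    """
    if n_animals < 1 or trials_per_animal < 1:
        raise ValueError("need at least one animal and one trial")
    if base is None:
        base = SyntheticTrialSpec()
    rng = np.random.default_rng(seed)
    trials: list[SyntheticTrial] = []
    lo, hi = F_DOM_RANGE
    a_, b_ = (lo - F_DOM_CENTER) / F_DOM_SD, (hi - F_DOM_CENTER) / F_DOM_SD
    quantiles = (np.arange(n_animals) + 0.5) / n_animals
    animal_f = truncnorm.ppf(quantiles, a_, b_, loc=F_DOM_CENTER, scale=F_DOM_SD)
    animal_f = rng.permutation(animal_f)
    for a in range(n_animals):
        gain = np.clip(
            1.0 + 0.25 * rng.standard_normal(base.n_harmonics + 1), 0.2, None
        )
        gain[base.n_dom] = 1.0
        spec = replace(base, f_dom=float(animal_f[a]), harmonic_gain=tuple(gain))
        for _ in range(trials_per_animal):
            trial_seed = int(rng.integers(0, 2**31 - 1))
            trials.append(generate_trial(spec, seed=trial_seed))

    L = base.n_harmonics
    spectra = {
        "hs": np.stack(
            [analysis.amplitude_spectrum(tr.hs, base.fs, base.T, L=L) for tr in trials]
        ),
        "sp": np.stack(
            [analysis.amplitude_spectrum(tr.sp, base.fs, base.T, L=L) for tr in trials]
        ),
    }
    summary = {
        joint: {
            "mean": m.mean(axis=0),
            "sd": m.std(axis=0, ddof=1) if len(trials) > 1 else np.zeros(m.shape[1]),
            "min": m.min(axis=0),
            "max": m.max(axis=0),
        }
        for joint, m in spectra.items()
    }
    return Population(
        trials=trials, spectra=spectra, summary=summary, animal_f_dom=animal_f
    )


# ---------------------------------------------------------------------------
# packaged default patterns (the representative Mc spectrum and the
# population summaries behind Mm / Mmsd)


def default_mc_pattern(joint: str = "hs", aligned: bool = True) -> FourierPattern:
    """Packaged single-trial (Mc) pattern for a joint.

    Fitted from a noise-free representative trial generated at the 1.5625 Hz
    analysis bin with the default harmonic profile and a fixed seed; the
    trial-to-trial variability of Mc runs then comes from the oscillator
    amplitude/frequency stochasticity, as in the model.
    """
    if joint not in ("hs", "sp"):
        raise ValueError("joint must be 'hs' or 'sp'")
    spec = SyntheticTrialSpec(f_cycle_sd=0.0)
    clean = replace(
        spec,
        hs=replace(spec.hs, upper_sd=0.0, lower_sd=0.0),
        sp=replace(spec.sp, upper_sd=0.0, lower_sd=0.0),
    )
    trial = generate_trial(clean, seed=DEFAULT_DATA_SEED)
    trace = trial.hs if joint == "hs" else trial.sp
    pattern = fit_fourier(trace, fs=clean.fs, T=clean.T, L=clean.n_harmonics)
    return pattern.align_dominant() if aligned else pattern


@functools.lru_cache(maxsize=4)
def default_variants(
    seed: int = DEFAULT_DATA_SEED,
) -> dict[str, dict[str, PatternVariant]]:
    """Pattern variants per joint built from the packaged default data.

    Returns ``{"hs": {"Mc": ..., "Mm": ..., "Mmsd": ...}, "sp": {...}}``.
    Mm uses the population-mean magnitudes with the phase spectrum of the
    representative Mc trial (magnitude averages carry no phase of their
    own); Mmsd adds the per-harmonic magnitude SDs.
    """
    pop = generate_population(seed=seed)
    out: dict[str, dict[str, PatternVariant]] = {}
    for joint in ("hs", "sp"):
        mc = default_mc_pattern(joint)
        mean_mags = np.array(pop.summary[joint]["mean"], dtype=float)
        sd_mags = np.array(pop.summary[joint]["sd"], dtype=float)
        mean_mags = mean_mags.copy()
        mean_mags[0] = 0.0
        mm_pattern = mc.with_magnitudes(mean_mags).align_dominant()
        out[joint] = {
            "Mc": PatternVariant(kind="Mc", base=mc),
            "Mm": PatternVariant(kind="Mm", base=mm_pattern),
            "Mmsd": PatternVariant(kind="Mmsd", base=mm_pattern, magnitude_sd=sd_mags),
        }
    return out
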