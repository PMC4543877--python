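# Methods

## The model in brief

The controller is a two-level central pattern generator.  The
*rhythm-generating* level is a chain of five Hopf oscillators in polar form
(left SP — left HS — neck — right HS — right SP), each holding an amplitude
`r` that relaxes to `μ`, an unwrapped phase `θ` advancing at the intrinsic
frequency `v` plus diffusive coupling `Σ w·sin(θⱼ−θᵢ−φᵢⱼ)`, and an offset
`c` relaxing to `C`.  The *pattern-formation* level maps phase to waveform
through a truncated Fourier series and produces the drive signal
`x = c + A_eff·F(θ)` that velocity-servo joints track on the skeletal
model.

A Hopf oscillator is used because its limit cycle gives independent,
explicit control over amplitude, frequency and phase — the three quantities
the biological questions are about.  The model deliberately contains no
muscles, no sensory feedback and no contact events; proprioceptor ablation
is represented purely as a change of `μ` and `C`.

## Oscillator parameters

| parameter | HS | SP | neck | units |
| --- | --- | --- | --- | --- |
| intrinsic frequency `v` | 1.45 ± 0.05 | 1.45 ± 0.05 | 1.25 ± 0.02 | Hz |
| amplitude `μ` (intact) | 39, U 8 / L 9 | 31, U 9 / L 15 | 6, U 1 / L 1 | deg |
| amplitude `μ` (ablated) | 55, U 16 / L 12 | 50, U 13 / L 18 | 6, U 1 / L 1 | deg |
| offset `C` (intact) | −60 | +22 | 0 | deg |
| offset `C` (ablated) | −72 | +15 | 0 | deg |
| gains `γ = γᶜ` | 20 | 20 | 50 | 1/s |

Offsets are given for the left antenna and sign-inverted on the right.
"U"/"L" are the standard deviations of the upper and lower oscillation
bounds; the "±" on `v` is the per-cycle frequency jitter.  Coupling:
`φ₁₂ = −π/9`, `w₁₂ = w₂₁ = 20`; `φ₂₃ = −π/3`, `w₂₃ = w₃₂ = 1`;
`φ₃₄ = 4π/3`, `w₃₄ = w₄₃ = 1`; `φ₄₅ = π/9`, `w₄₅ = w₅₄ = 20`.  Edges come
in antisymmetric pairs (bias `φ` one way, `−φ` the other), which makes
`Δθ = φ` the stable fixed point of each pair.

Two consequences of this parameter set are worth spelling out.  First, the
locked network runs at the weighted compromise frequency
`(4·1.45 + 1.25)/5 = 1.41 Hz`, not at 1.45 Hz: the neck oscillator is
pulled up by ~0.16 Hz and the antennal ones down by 0.04 Hz.  Second, the
frequency mismatch across the weak neck edges shifts their steady phase
differences away from the biases by `±asin(…) ≈ ±30°` — but the two shifts
are equal and opposite, so the left–right HS separation still composes to
exactly `φ₂₃ + φ₃₄ = 180°`.  The strong intra-antennal edges are shifted by
only `asin(2π·0.04/40) ≈ 0.7°`, so the realized SP lead is ≈20.7° rather
than exactly 20°.

## Stochasticity schedule

The published description places the noise on the amplitude variable
without fixing a schedule.  Here the *upper* effective amplitude is
re-drawn from `Normal(μ, U)` at each upward zero crossing of `F`, the
*lower* one from `Normal(μ, L)` at each downward crossing, and the
effective intrinsic frequency from `Normal(v, v_sd)` once per full cycle of
`θ`.  Amplitude draws are truncated at zero (a negative radius is
meaningless in polar form).  Because the envelope switches between the two
draws exactly where `F = 0`, the drive signal stays continuous.  In the
deterministic limit (U = L = v_sd = 0) the drive reduces to the textbook
`x = c + r·F(θ)`.

## Radial integration mode

With amplitudes in degrees, the literal radial equation has a relaxation
rate `2γμ² ≈ 6·10⁴ /s` for the antennal joints — far beyond what the fixed
5 ms RK2 step can integrate (the blow-up guard aborts when `|r| > 10 μ`).
The default mode therefore integrates the amplitude-normalized form
`ṙ = γ(1−(r/μ)²)r`, which has the same fixed point `r* = μ` and sign
structure but a μ-independent rate `2γ = 40 /s`, comfortably stable at
5 ms.  The literal form remains available (`radial_mode="literal"`) for
small-`μ` or small-step work.  All phase and offset dynamics are identical
in both modes; no steady-state result depends on the choice.

## Pattern phase convention

The pattern series is evaluated at `Ψ = θ / n_dom`, where `n_dom` is the
dominant harmonic index of the fitted window (8 for the default 5.12 s
window).  With this convention the dominant component `sin(n_dom Ψ) =
sin(θ)` oscillates at the oscillator's intrinsic frequency and the full
pattern repeats every `n_dom` cycles (≈5.5 s at 1.45 Hz), consistent with
the analysis-window length.  Evaluating the series directly in `θ` would
put the dominant component at 8× the joint frequency, which is not a
physically meaningful reading.

Patterns fitted from recordings are **dominant-aligned** before being
installed in the CPG: the pattern phase is rotated so the dominant harmonic
is a pure sine of `θ`.  Without this, the ~20° SP lead already present in
the recorded traces would add to the 20° oscillator bias and the model
would express a ~40° lead.  Alignment is a pure time shift of the waveform;
it changes no magnitudes.

The DC term is fitted (for reconstruction) but excluded from `F`: the mean
joint position is carried solely by the offset state `c`, avoiding double
counting.  Normalization is to unit *peak* (`max|F| = 1`, located to
machine precision by bounded refinement of a 4096-point grid search), which
makes `μ` the half-range of the joint excursion in degrees.

## Pattern variants

* `Mc` — the packaged representative single-trial spectrum, fitted from a
  noise-free surrogate trial at the 1.5625 Hz bin with a fixed seed.  Run-
  to-run variability of Mc simulations comes from the oscillator
  stochasticity, not from the pattern.
* `Mm` — population-mean magnitudes.  A mean of magnitudes carries no phase
  information of its own, so the phase spectrum of the Mc pattern is
  attached before re-normalization.
* `Mmsd` — `Mm` plus, per sampled pattern, Gaussian perturbation of each
  harmonic magnitude with the population's per-harmonic SD (truncated at
  zero, phases preserved).  HS and SP draw independently, which is what
  destroys their waveform match and degrades the cross-correlogram.
* `triangular` — sine-only triangle wave (`b ∝ (−1)ᵏ/(2k+1)²` at odd
  multiples of `n_dom`); a waveform with a unique phase spectrum.
* `augmented` — the same harmonics duplicated into the cosine terms with
  equal magnitudes (the published construction states no cosine weights;
  equal magnitude is the documented choice).  This adds a second phase to
  the phase spectrum and skews the rise/fall of each half-wave.  Note that
  any waveform built from odd harmonics only — sines *and* cosines — is
  exactly half-wave antisymmetric, so the positive and negative half-wave
  *extrema* remain equal; the asymmetry introduced is of shape (time
  reversal), not of amplitude.

## Skeletal model and servos

Geometry (meters, external frame, initial posture): HS pivot
(0.0174, −0.0083, 0.0100), axis (−0.1480, 0.8430, 0.5140); SP pivot
(0.0342, −0.0066, 0.0100), axis (−0.1530, 0.8690, −0.4690); neck pivot
(−0.015, 0, 0), vertical axis.  Scape 17 mm, pedicel+flagellum 263 mm
(one rigid segment), spherical head of 40 mm diameter; masses (3, 12.5,
200 mg) are metadata only.  Both antennae start outstretched in the
horizontal plane, 10° medially; this angle is taken from the body axis at
the SP pivot.  The right side mirrors the left across y = 0 (pivot y and
axis y negated, hinge sense kept), so mirrored postures correspond to
sign-inverted angles — matching the sign inversion of the right-side
offsets.

Joint angle zero is the initial posture.  Since the tabulated axes are
valid only for that posture, distal axes co-rotate with proximal joints;
forward kinematics applies the rotations about the initial axes
distal-first (`tip = T_neck(T_hs(T_sp(tip₀)))`), the standard
product-of-exponentials composition.

Joints are first-order velocity servos,
`angle += clamp(K·(x − angle), ±rate_max)·dt`, updated at the CPG step.
Defaults `K = 380 /s`, `rate_max = 2000 °/s` were chosen so the tracking
error on the standard intact run is comfortably inside the published
bounds (HS ≈ 0.5° ≤ 1.5°, SP ≈ 0.4° ≤ 0.6° RMSE); the rate limit stands in
for the motor torque limit and is inactive during steady tracking.  `K·dt`
must stay below 2 for stability of the explicit update.

## Integration, sampling, trial protocol

Fixed-step midpoint RK2 at dt = 5 ms.  Initial conditions: `r = μ/2`,
`c = C`, phases uniform-random (seeded) or chain-aligned; a 5 s transient
is discarded from every analysis.  Standard trials simulate 60 s after the
transient (≈85 cycles, enough for stable correlogram averages) and are
resampled to 50 Hz — every 4th step, matching the motion-capture
convention.  Identical seeds give bit-identical trajectories.

## Analysis conventions

* **Sliding cross-correlogram**: Pearson correlation of the SP trace
  shifted by each lag in ±1 s against the HS trace in a ±1 s window, window
  centers every sample (20 ms).  Windows whose lag range would leave the
  trace are dropped, not zero-padded (padding attenuates the mean).  Zero-
  variance windows are recorded as undefined and excluded from the mean.
  A lead of the second trace appears at negative lag.
* **Lag→phase**: the central peak (within half a dominant period) of the
  mean correlogram, refined by a parabolic fit through its neighbors, is
  converted as `phase = −360·f_dom·lag`.  `f_dom` defaults to the dominant
  spectral frequency of the HS trace (full-length periodogram with
  parabolic bin interpolation) rather than a hard-coded 1.5625 Hz — the
  locked network runs at ≈1.41 Hz.
* **Circular statistics**: variance `1 − |⟨e^{iθ}⟩|`.  Inside simulations
  the oscillator phases are used directly; for external recordings a
  band-limited analytic-signal fallback (`[0.5, 1.5]·f_dom`) is provided.
* **Working range**: 5th–95th percentile span, linear interpolation.
* **Trajectory shape**: tip points are projected onto the plane orthogonal
  to the mean antennal direction; the shape ratio is
  `sqrt(λ_min/λ_max)` of the projected 2-D covariance (0 = line,
  1 = circle), with the major-axis orientation as secondary output.  This
  scalar quantifies the *width* of the tip pattern; it deliberately does
  not measure cycle-to-cycle irregularity, so a fat but incoherent pattern
  scores high.  Shape ratios are computed on the actual world-frame tips.

## Experiment suite

`run_condition` simulates one condition/variant and reports working ranges,
the mean correlogram and its peak, the recovered SP lead, tracking RMSEs
and the trajectory shape.  The intact→ablated switch re-parameterizes only
`μ`, `C` and their bound statistics (asserted by diffing the resolved
configurations).

`run_phase_sweep` varies the SP-vs-HS bias over
{−40, −20, 0, 10, 20, 40, 60, 90, 180}° on both antennae.  The Mc/Mm
sweeps run the full quasi-rhythmic model.  The triangular/augmented sweeps
are deterministic control experiments with the neck oscillation silenced
(`μ_neck = 0`): they isolate the phase relation of the two antennal joints,
and only under that isolation do the defining properties of the symmetric-
waveform control hold (trajectory width symmetric in ±lead; collapse to a
single line at 0° and 180°).  With the neck active, its ±6° yaw at a
~0.3 m lever adds a phase-locked third component that breaks both.

## The surrogate dataset

The generator emulates the *statistical structure* of the unpublished
recordings, not any individual animal: a harmonic stack around the dominant
bin with magnitudes decaying as `c/|n−n_dom| + baseline` (c = 0.15,
baseline = 0.02 — profile constants are exposed, not fitted), shared cycle
timing between HS and SP with a fixed 20° SP lead, per-half-cycle
upper/lower amplitude jitter with the tabulated U/L SDs, and per-cycle
frequency jitter.  Populations draw per-animal dominant frequencies as a
stratified truncated-normal sample (center 1.5625 Hz, SD 0.12 Hz, range
1.36–1.95 Hz) — quantile spacing keeps a 5-animal sample representative,
so the population-mean spectrum peaks at the dominant bin for any seed —
plus per-animal harmonic-gain multipliers (lognormal-like, SD 0.25).

What passing tests on surrogates do and do not show: they demonstrate that
the pipeline recovers imposed structure (phase leads, envelopes, spectra)
and that the model's orderings (ablated > intact working range; Mmsd
correlogram peak < Mc) hold under realistic variability.  They cannot
certify waveform-level agreement with real stick-insect recordings — the
"< 3°" reconstruction-fidelity bound is verified on surrogate, not animal,
traces.

## Known limitations

* No muscles, no contact events, no sensory feedback; ablation is a pure
  parameter change.  Head pitch/roll are absent (the neck has yaw only).
* The covariance-based shape ratio grows monotonically with the dominant-
  pair phase shift up to 90° (Lissajous widening) and therefore cannot, by
  construction, score the quasi-rhythmic pattern's *deterioration* at
  large leads below its widening; a per-cycle coherence metric would be
  needed for that distinction.
* The rate-limited first-order servo reproduces the published tracking-
  error contract, not the torque dynamics of the original rigid-body
  simulation; masses are carried as metadata only.
* `Mm`'s phase spectrum is by construction that of the representative
  trial; alternatives (e.g. circular-mean phases across trials) were not
  explored.
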