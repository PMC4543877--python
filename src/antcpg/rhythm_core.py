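"""Rhythm-generating network: phase-coupled Hopf oscillators.

Five oscillators — left SP, left HS, neck, right HS, right SP — form a chain
with diffusive phase coupling.  Each oscillator carries three state
variables in polar form,

    dr/dt     = gamma * (mu^2 - r^2) * r
    dtheta/dt = 2*pi*v + sum_j w_ij * sin(theta_j - theta_i - phi_ij)
    dc/dt     = gamma_c * (C - c)

i.e. an amplitude that relaxes to ``mu`` (degrees), a phase that advances at
the intrinsic frequency ``v`` (Hz) while being pulled toward the phase bias
``phi_ij`` relative to each coupled neighbor, and an offset that relaxes to
``C`` (degrees).  The drive signal handed to the servo joints is

    x = c + A_eff * F(theta)

with ``F`` the normalized pattern of :mod:`antcpg.pattern_formation` and
``A_eff`` the current effective amplitude: quasi-rhythmicity is produced by
re-drawing the amplitude that gates positive excursions of ``F`` from
``Normal(mu, U)`` at each upward zero crossing of ``F``, the one gating
negative excursions from ``Normal(mu, L)`` at each downward crossing (so x
stays continuous), and the intrinsic frequency from ``Normal(v, v_sd)`` once
per full cycle.  Noise off (U = L = v_sd = 0) recovers the deterministic
limit ``x = c + r F(theta)`` at steady state.

Integration uses the midpoint (second-order Runge-Kutta) method with a fixed
5 ms step.  With amplitudes expressed in degrees the literal radial equation
has a relaxation rate ``2*gamma*mu^2 ~ 6e4 /s`` and is unintegrable at that
step, so the default ``radial_mode="normalized"`` integrates the equivalent
form ``dr/dt = gamma*(1-(r/mu)^2)*r`` (identical fixed point ``r* = mu``,
rate ``2*gamma = 40 /s``).  The literal form is available as
``radial_mode="literal"`` and is guarded by a blow-up check.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pattern_formation import FourierPattern

__all__ = [
    "OscillatorParams",
    "OscillatorState",
    "CouplingEdge",
    "NetworkSpec",
    "NetworkTrajectory",
    "NumericalBlowUpError",
    "OSCILLATOR_NAMES",
    "coupling_pair",
    "default_network",
    "hopf_derivatives",
    "drive_signal",
    "resample_amplitudes",
    "step_rk2",
    "simulate_network",
    "relax_radius",
    "network_from_dict",
    "network_to_dict",
]

#: canonical oscillator ordering (indices 0..4 = network nodes 1..5)
OSCILLATOR_NAMES = ("sp_left", "hs_left", "neck", "hs_right", "sp_right")

TWO_PI = 2.0 * np.pi

#: integration aborts when |r| exceeds this multiple of mu
BLOWUP_FACTOR = 10.0


class NumericalBlowUpError(RuntimeError):
    """Raised when the integration leaves the physically meaningful region,
    typically because the time step is too large for the given gains."""


# ---------------------------------------------------------------------------
# parameter and state containers


@dataclass(frozen=True)
class OscillatorParams:
    """Per-joint Hopf oscillator parameters.

    Attributes
    ----------
    v : float
        Intrinsic frequency in Hz.
    mu : float
        Target amplitude in degrees (half-range of the joint oscillation).
    C : float
        Target offset in degrees (mean angle of oscillation).
    gamma, gamma_c : float
        Convergence gains (1/s) of the amplitude and offset dynamics.
    U, L_sd : float
        Standard deviations (degrees) of the per-cycle variation of the
        upper and lower bounds of the joint angle time course.
    v_sd : float
        Standard deviation (Hz) of the per-cycle intrinsic frequency draws
        (the "+/-" of the frequency entries).
    """

    v: float
    mu: float
    C: float
    gamma: float = 20.0
    gamma_c: float = 20.0
    U: float = 0.0
    L_sd: float = 0.0
    v_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.gamma_c <= 0:
            raise ValueError("gamma and gamma_c must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if min(self.U, self.L_sd, self.v_sd) < 0:
            raise ValueError("U, L_sd and v_sd must be non-negative")

    def deterministic(self) -> "OscillatorParams":
        """Copy with all stochasticity switched off."""
        return replace(self, U=0.0, L_sd=0.0, v_sd=0.0)


@dataclass(frozen=True)
class OscillatorState:
    """State of one oscillator: radius (deg), unwrapped phase (rad), offset
    (deg) plus the current effective amplitude draws (deg)."""

    r: float
    theta: float
    c: float
    amp_upper: float
    amp_lower: float
    v_eff: float

    @classmethod
    def initial(cls, params: OscillatorParams, theta: float = 0.0) -> "OscillatorState":
        return cls(
            r=params.mu / 2.0,
            theta=theta,
            c=params.C,
            amp_upper=params.mu,
            amp_lower=params.mu,
            v_eff=params.v,
        )


@dataclass(frozen=True)
class CouplingEdge:
    """Directed coupling j -> i contributing
    ``weight * sin(theta_source - theta_target - phase_bias)`` to the target
    phase velocity."""

    source: int
    target: int
    weight: float
    phase_bias: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("coupling weight must be non-negative")
        if self.source == self.target:
            raise ValueError("self-coupling is not allowed")


def coupling_pair(i: int, j: int, weight: float, bias: float) -> tuple[CouplingEdge, CouplingEdge]:
    """Antisymmetric bidirectional coupling between oscillators ``i`` and
    ``j``: edge j->i with bias ``phi_ij = bias`` and edge i->j with ``-bias``
    (the structure of the connection matrix)."""
    return (
        CouplingEdge(source=j, target=i, weight=weight, phase_bias=bias),
        CouplingEdge(source=i, target=j, weight=weight, phase_bias=-bias),
    )


@dataclass(frozen=True)
class NetworkSpec:
    """The 5-oscillator chain with integration settings.

    The default topology is the chain 1-2-3-4-5 (left SP, left HS, neck,
    right HS, right SP) with strong intra-antennal coupling (w = 20) and weak
    coupling through the neck (w = 1).
    """

    oscillators: tuple[OscillatorParams, ...]
    edges: tuple[CouplingEdge, ...]
    dt: float = 0.005
    radial_mode: str = "normalized"
    init: str = "random"

    def __post_init__(self) -> None:
        object.__setattr__(self, "oscillators", tuple(self.oscillators))
        object.__setattr__(self, "edges", tuple(self.edges))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.radial_mode not in ("normalized", "literal"):
            raise ValueError("radial_mode must be 'normalized' or 'literal'")
        if self.init not in ("random", "aligned"):
            raise ValueError("init must be 'random' or 'aligned'")
        n = len(self.oscillators)
        seen = {}
        for e in self.edges:
            if not (0 <= e.source < n and 0 <= e.target < n):
                raise ValueError("edge endpoint outside oscillator range")
            seen[(e.source, e.target)] = e
        for (s, t), e in seen.items():
            rev = seen.get((t, s))
            if rev is None or abs(rev.phase_bias + e.phase_bias) > 1e-12:
                raise ValueError(
                    "edges must occur in antisymmetric pairs: "
                    f"edge {s}->{t} has no partner with bias -phi"
                )

    @property
    def n(self) -> int:
        return len(self.oscillators)

    def deterministic(self) -> "NetworkSpec":
        """Copy with all stochasticity off (for noise-free analyses)."""
        return replace(
            self, oscillators=tuple(p.deterministic() for p in self.oscillators)
        )


# ---------------------------------------------------------------------------
# default parameterization (intact / hair-field-ablated conditions)

_INTACT = {
    "hs": dict(v=1.45, mu=39.0, C=-60.0, gamma=20.0, gamma_c=20.0, U=8.0, L_sd=9.0, v_sd=0.05),
    "sp": dict(v=1.45, mu=31.0, C=22.0, gamma=20.0, gamma_c=20.0, U=9.0, L_sd=15.0, v_sd=0.05),
    "neck": dict(v=1.25, mu=6.0, C=0.0, gamma=50.0, gamma_c=50.0, U=1.0, L_sd=1.0, v_sd=0.02),
}
_ABLATED = {
    "hs": dict(v=1.45, mu=55.0, C=-72.0, gamma=20.0, gamma_c=20.0, U=16.0, L_sd=12.0, v_sd=0.05),
    "sp": dict(v=1.45, mu=50.0, C=15.0, gamma=20.0, gamma_c=20.0, U=13.0, L_sd=18.0, v_sd=0.05),
    "neck": dict(v=1.25, mu=6.0, C=0.0, gamma=50.0, gamma_c=50.0, U=1.0, L_sd=1.0, v_sd=0.02),
}

#: default phase biases (rad) and weights of the chain, node pairs 1-indexed:
#: phi_12 = -pi/9, w = 20; phi_23 = -pi/3, w = 1; phi_34 = 4*pi/3, w = 1;
#: phi_45 = pi/9, w = 20.  The composition phi_23 + phi_34 = pi puts left and
#: right HS oscillators 180 deg apart; phi_45 (and -phi_12) give the SP joint
#: a 20 deg phase lead over its HS joint.
DEFAULT_COUPLING = (
    (0, 1, 20.0, -np.pi / 9.0),
    (1, 2, 1.0, -np.pi / 3.0),
    (2, 3, 1.0, 4.0 * np.pi / 3.0),
    (3, 4, 20.0, np.pi / 9.0),
)


def default_network(
    condition: str = "intact",
    stochastic: bool = True,
    dt: float = 0.005,
    radial_mode: str = "normalized",
    init: str = "random",
) -> NetworkSpec:
    """Build the default five-oscillator network for a study condition.

    Offsets are given for the left antenna and sign-inverted on the right;
    frequency and amplitude parameters are shared between sides.  With
    ``stochastic=False`` all U/L/frequency jitter SDs are zeroed.
    """
    table = {"intact": _INTACT, "ablated": _ABLATED}.get(condition)
    if table is None:
        raise ValueError("condition must be 'intact' or 'ablated'")

    def mk(joint: str, side: int) -> OscillatorParams:
        kw = dict(table[joint])
        kw["C"] = side * kw["C"]
        p = OscillatorParams(**kw)
        return p if stochastic else p.deterministic()

    oscillators = (
        mk("sp", +1),  # 1: left SP
        mk("hs", +1),  # 2: left HS
        mk("neck", +1),  # 3: neck
        mk("hs", -1),  # 4: right HS
        mk("sp", -1),  # 5: right SP
    )
    edges: list[CouplingEdge] = []
    for i, j, w, phi in DEFAULT_COUPLING:
        edges.extend(coupling_pair(i, j, w, phi))
    return NetworkSpec(
        oscillators=oscillators,
        edges=tuple(edges),
        dt=dt,
        radial_mode=radial_mode,
        init=init,
    )


# ---------------------------------------------------------------------------
# single-oscillator operations


def _radial_rate(r: float | np.ndarray, params_mu, params_gamma, mode: str):
    if mode == "literal":
        return params_gamma * (params_mu**2 - r**2) * r
    # normalized: same fixed point, mu-independent relaxation rate 2*gamma
    mu_safe = np.where(np.asarray(params_mu) > 0, params_mu, 1.0)
    rho2 = (r / mu_safe) ** 2
    return np.where(
        np.asarray(params_mu) > 0, params_gamma * (1.0 - rho2) * r, -params_gamma * r
    )


def hopf_derivatives(
    state: OscillatorState,
    params: OscillatorParams,
    neighbor_phases: list[tuple[float, float, float]] = (),
    radial_mode: str = "literal",
) -> tuple[float, float, float]:
    """Time derivatives (dr/dt, dtheta/dt, dc/dt) of one oscillator.

    ``neighbor_phases`` lists ``(theta_j, w_ij, phi_ij)`` triples; each
    contributes ``w_ij * sin(theta_j - theta_i - phi_ij)`` to the phase
    velocity.
    """
    if not np.isfinite([state.r, state.theta, state.c]).all():
        raise NumericalBlowUpError(
            "non-finite oscillator state: the time step is probably too large "
            "for the configured gamma / coupling weights"
        )
    coupling = 0.0
    for theta_j, w, phi in neighbor_phases:
        if w < 0:
            raise ValueError("coupling weights must be non-negative")
        coupling += w * np.sin(theta_j - state.theta - phi)
    dr = float(_radial_rate(state.r, params.mu, params.gamma, radial_mode))
    dtheta = TWO_PI * state.v_eff + coupling
    dc = params.gamma_c * (params.C - state.c)
    return dr, dtheta, dc


def drive_signal(state: OscillatorState, pattern: FourierPattern) -> float:
    """Driving signal ``x = c + A_eff * F(theta)`` in degrees.

    The effective amplitude is the current upper draw while ``F`` is
    positive and the lower draw while it is negative; the switch happens at
    ``F = 0`` so ``x`` is continuous.
    """
    if not pattern.normalized:
        raise ValueError("pattern must be normalized (scaling M applied)")
    F = float(pattern.evaluate(state.theta))
    amp = state.amp_upper if F >= 0 else state.amp_lower
    return state.c + amp * F


def resample_amplitudes(
    state: OscillatorState,
    params: OscillatorParams,
    rng: np.random.Generator,
    events: tuple[str, ...] = ("upper", "lower", "frequency"),
) -> OscillatorState:
    """Re-draw the stochastic oscillator quantities.

    ``upper``/``lower`` draw the effective amplitudes from
    ``Normal(mu, U)`` / ``Normal(mu, L)`` truncated at 0; ``frequency``
    draws the effective intrinsic frequency from ``Normal(v, v_sd)``.
    During a simulation ``upper`` fires at each upward zero crossing of F,
    ``lower`` at each downward crossing, and ``frequency`` once per full
    cycle of theta.
    """
    amp_upper, amp_lower, v_eff = state.amp_upper, state.amp_lower, state.v_eff
    if "upper" in events:
        amp_upper = max(0.0, params.mu + params.U * rng.standard_normal())
    if "lower" in events:
        amp_lower = max(0.0, params.mu + params.L_sd * rng.standard_normal())
    if "frequency" in events:
        v_eff = params.v + params.v_sd * rng.standard_normal()
    return replace(state, amp_upper=amp_upper, amp_lower=amp_lower, v_eff=v_eff)


def relax_radius(
    params: OscillatorParams,
    r0: float = 1.0,
    dt: float = 0.005,
    radial_mode: str = "normalized",
    tol: float = 1e-9,
    max_time: float = 120.0,
) -> float:
    """Integrate the radial equation of a single uncoupled oscillator until
    ``|dr/dt| < tol`` and return the attained radius (degrees).

    From any positive start this converges to the Hopf fixed point
    ``r* = mu``.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive (polar form)")
    r = float(r0)
    steps = int(round(max_time / dt))
    scale = max(params.mu, 1.0)
    for _ in range(steps):
        # sub-step while the cubic is locally fast relative to the radius
        # scale, so far-from-fixed-point starts stay on the attractor; the
        # requested dt is the outer (reporting) step
        remaining = dt
        while remaining > 0:
            k1 = float(_radial_rate(r, params.mu, params.gamma, radial_mode))
            h = remaining
            if abs(k1) * h > 0.05 * scale:
                h = 0.05 * scale / abs(k1)
            k2 = float(
                _radial_rate(r + 0.5 * h * k1, params.mu, params.gamma, radial_mode)
            )
            r = r + h * k2
            remaining -= h
            if not np.isfinite(r) or abs(r) > BLOWUP_FACTOR * scale:
                raise NumericalBlowUpError(
                    f"radial integration diverged (r={r!r}); decrease dt or "
                    "use radial_mode='normalized'"
                )
        if abs(_radial_rate(r, params.mu, params.gamma, radial_mode)) < tol:
            break
    return r


# ---------------------------------------------------------------------------
# network integration


class _PatternBank:
    """Padded coefficient matrices for evaluating all patterns at once."""

    def __init__(self, patterns: list[FourierPattern]):
        for p in patterns:
            if not p.normalized:
                raise ValueError("all patterns must be normalized")
        Lmax = max(p.L for p in patterns)
        n = len(patterns)
        self.A = np.zeros((n, Lmax + 1))
        self.B = np.zeros((n, Lmax + 1))
        self.M = np.array([p.M for p in patterns])
        self.n_dom = np.array([p.n_dom for p in patterns], dtype=float)
        for k, p in enumerate(patterns):
            self.A[k, 1 : p.L + 1] = p.a[1:]
            self.B[k, 1 : p.L + 1] = p.b[1:]
        self.harm = np.arange(Lmax + 1, dtype=float)

    def evaluate(self, theta: np.ndarray) -> np.ndarray:
        psi = theta / self.n_dom
        ang = psi[:, None] * self.harm[None, :]
        return self.M * (
            np.einsum("ij,ij->i", self.A, np.cos(ang))
            + np.einsum("ij,ij->i", self.B, np.sin(ang))
        )


def _resolve_patterns(
    patterns, n: int
) -> list[FourierPattern]:
    if isinstance(patterns, dict):
        missing = [name for name in OSCILLATOR_NAMES[:n] if name not in patterns]
        if missing:
            raise ValueError(f"patterns missing for oscillators {missing}")
        return [patterns[name] for name in OSCILLATOR_NAMES[:n]]
    patterns = list(patterns)
    if len(patterns) != n:
        raise ValueError("need one pattern per oscillator")
    return patterns


@dataclass
class _ArrayState:
    r: np.ndarray
    theta: np.ndarray
    c: np.ndarray
    v_eff: np.ndarray
    amp_upper: np.ndarray
    amp_lower: np.ndarray


def _spec_arrays(spec: NetworkSpec):
    p = spec.oscillators
    return {
        "v": np.array([q.v for q in p]),
        "mu": np.array([q.mu for q in p]),
        "C": np.array([q.C for q in p]),
        "gamma": np.array([q.gamma for q in p]),
        "gamma_c": np.array([q.gamma_c for q in p]),
        "U": np.array([q.U for q in p]),
        "L_sd": np.array([q.L_sd for q in p]),
        "v_sd": np.array([q.v_sd for q in p]),
        "esrc": np.array([e.source for e in spec.edges], dtype=int),
        "edst": np.array([e.target for e in spec.edges], dtype=int),
        "ew": np.array([e.weight for e in spec.edges]),
        "ephi": np.array([e.phase_bias for e in spec.edges]),
    }


def step_rk2(
    state: _ArrayState, spec: NetworkSpec, dt: float | None = None, _pa=None
) -> _ArrayState:
    """One deterministic midpoint (RK2) step of the full coupled system.

    Stochastic resampling happens only in :func:`resample_amplitudes`; given
    identical state this step is bit-reproducible.
    """
    pa = _pa if _pa is not None else _spec_arrays(spec)
    dt = spec.dt if dt is None else dt
    nosc = spec.n

    def derivs(r, th, c):
        coup = np.zeros(nosc)
        if pa["esrc"].size:
            np.add.at(
                coup,
                pa["edst"],
                pa["ew"] * np.sin(th[pa["esrc"]] - th[pa["edst"]] - pa["ephi"]),
            )
        dr = _radial_rate(r, pa["mu"], pa["gamma"], spec.radial_mode)
        dth = TWO_PI * state.v_eff + coup
        dc = pa["gamma_c"] * (pa["C"] - c)
        return dr, dth, dc

    k1r, k1t, k1c = derivs(state.r, state.theta, state.c)
    hm = 0.5 * dt
    k2r, k2t, k2c = derivs(state.r + hm * k1r, state.theta + hm * k1t, state.c + hm * k1c)
    new = _ArrayState(
        r=state.r + dt * k2r,
        theta=state.theta + dt * k2t,
        c=state.c + dt * k2c,
        v_eff=state.v_eff.copy(),
        amp_upper=state.amp_upper.copy(),
        amp_lower=state.amp_lower.copy(),
    )
    if not (
        np.all(np.isfinite(new.r))
        and np.all(np.isfinite(new.theta))
        and np.all(np.isfinite(new.c))
    ):
        raise NumericalBlowUpError(
            "non-finite network state after RK2 step; dt too large for the "
            "configured gamma / coupling weights"
        )
    mu = pa["mu"]
    if np.any(np.abs(new.r) > BLOWUP_FACTOR * np.maximum(mu, 1.0)):
        raise NumericalBlowUpError(
            "oscillator radius exceeded 10*mu: the radial equation is stiff at "
            "this dt (consider radial_mode='normalized' or a smaller step)"
        )
    return new


@dataclass
class NetworkTrajectory:
    """Recorded state trajectory at the integration step resolution.

    Arrays have shape ``(n_steps+1, n_osc)``; ``theta`` is unwrapped.
    ``x`` is the drive signal (deg) and ``F`` the normalized pattern value.
    """

    time: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    c: np.ndarray
    x: np.ndarray
    F: np.ndarray
    spec: NetworkSpec = field(repr=False)

    def theta_wrapped(self) -> np.ndarray:
        return np.mod(self.theta, TWO_PI)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_s": self.time}
        wrapped = self.theta_wrapped()
        for k, name in enumerate(OSCILLATOR_NAMES[: self.spec.n]):
            cols[f"r_{name}"] = self.r[:, k]
            cols[f"theta_wrapped_{name}"] = wrapped[:, k]
            cols[f"c_{name}"] = self.c[:, k]
            cols[f"x_{name}"] = self.x[:, k]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _initial_state(spec: NetworkSpec, pa, rng: np.random.Generator) -> _ArrayState:
    n = spec.n
    if spec.init == "random":
        theta = rng.uniform(0.0, TWO_PI, size=n)
    else:  # aligned: chain-consistent phases (the locked pattern)
        theta = np.zeros(n)
        bias = {}
        for e in spec.edges:
            bias[(e.target, e.source)] = e.phase_bias
        for k in range(1, n):
            theta[k] = theta[k - 1] + bias.get((k - 1, k), 0.0)
    return _ArrayState(
        r=pa["mu"] / 2.0,
        theta=theta,
        c=pa["C"].copy(),
        v_eff=pa["v"].copy(),
        amp_upper=pa["mu"].copy(),
        amp_lower=pa["mu"].copy(),
    )


def simulate_network(
    spec: NetworkSpec,
    patterns,
    duration: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NetworkTrajectory:
    """Integrate the coupled network for ``duration`` seconds.

    Parameters
    ----------
    spec : NetworkSpec
    patterns : dict or sequence
        One normalized :class:`FourierPattern` per oscillator, keyed by
        oscillator name or given in canonical order.
    duration : float
        Simulated time in seconds; the trajectory is recorded at every
        integration step (``spec.dt``).
    seed, rng
        Source of randomness for the initial phases, amplitude draws and
        frequency jitter.  Identical seeds produce bit-identical
        trajectories.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    pats = _resolve_patterns(patterns, spec.n)
    bank = _PatternBank(pats)
    pa = _spec_arrays(spec)
    n = spec.n
    n_steps = int(round(duration / spec.dt))

    state = _initial_state(spec, pa, rng)
    # initial draws so the first cycle is already stochastic
    for i in range(n):
        state.amp_upper[i] = max(0.0, pa["mu"][i] + pa["U"][i] * rng.standard_normal())
        state.amp_lower[i] = max(0.0, pa["mu"][i] + pa["L_sd"][i] * rng.standard_normal())
        state.v_eff[i] = pa["v"][i] + pa["v_sd"][i] * rng.standard_normal()

    theta0 = state.theta.copy()
    cycles = np.zeros(n, dtype=int)

    time = np.arange(n_steps + 1) * spec.dt
    R = np.empty((n_steps + 1, n))
    TH = np.empty((n_steps + 1, n))
    CC = np.empty((n_steps + 1, n))
    X = np.empty((n_steps + 1, n))
    FF = np.empty((n_steps + 1, n))

    F_prev = bank.evaluate(state.theta)

    def record(k, F):
        R[k] = state.r
        TH[k] = state.theta
        CC[k] = state.c
        FF[k] = F
        amp = np.where(F >= 0.0, state.amp_upper, state.amp_lower)
        X[k] = state.c + amp * F

    record(0, F_prev)
    for k in range(1, n_steps + 1):
        state = step_rk2(state, spec, _pa=pa)
        F_new = bank.evaluate(state.theta)
        # stochastic schedule: fixed oscillator order for reproducibility
        new_cycles = np.floor((state.theta - theta0) / TWO_PI).astype(int)
        for i in range(n):
            if F_prev[i] < 0.0 <= F_new[i]:
                state.amp_upper[i] = max(
                    0.0, pa["mu"][i] + pa["U"][i] * rng.standard_normal()
                )
            elif F_prev[i] > 0.0 >= F_new[i]:
                state.amp_lower[i] = max(
                    0.0, pa["mu"][i] + pa["L_sd"][i] * rng.standard_normal()
                )
            if new_cycles[i] > cycles[i]:
                state.v_eff[i] = pa["v"][i] + pa["v_sd"][i] * rng.standard_normal()
                cycles[i] = new_cycles[i]
        record(k, F_new)
        F_prev = F_new

    return NetworkTrajectory(time=time, r=R, theta=TH, c=CC, x=X, F=FF, spec=spec)


# ---------------------------------------------------------------------------
# configuration dictionaries (for the YAML interface of the CLI)


def network_to_dict(spec: NetworkSpec) -> dict:
    return {
        "dt": spec.dt,
        "radial_mode": spec.radial_mode,
        "init": spec.init,
        "oscillators": [
            dict(name=OSCILLATOR_NAMES[k] if k < 5 else f"osc{k}", **dataclasses.asdict(p))
            for k, p in enumerate(spec.oscillators)
        ],
        "edges": [dataclasses.asdict(e) for e in spec.edges],
    }


def network_from_dict(d: dict) -> NetworkSpec:
    oscillators = tuple(
        OscillatorParams(**{k: v for k, v in o.items() if k != "name"})
        for o in d["oscillators"]
    )
    edges = tuple(CouplingEdge(**e) for e in d["edges"])
    return NetworkSpec(
        oscillators=oscillators,
        edges=edges,
        dt=d.get("dt", 0.005),
        radial_mode=d.get("radial_mode", "normalized"),
        init=d.get("init", "random"),
    )
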