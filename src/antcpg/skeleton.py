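"""Head-antenna kinematic chain and servo joints.

The skeletal model comprises a spherical head on a vertical-axis neck (yaw
only) and two antennae, each with two hinge joints: head-scape (HS) and
scape-pedicel (SP).  The antennal hinge axes are slanted and non-orthogonal;
pivots and axes are specified in the external frame for the initial posture,
in which both antennae are outstretched in the horizontal plane at 10 deg
facing medially.  Pedicel and flagellum are lumped into one rigid distal
segment.  Left-side geometry is mirrored across the sagittal plane (y = 0)
for the right side.

Joint angle zero corresponds to the initial posture; a positive angle is a
right-hand rotation about the stated axis.  Because the SP axis and pivot
are rigidly attached to the scape (and the antennal joints to the head),
the world position of a distal point is obtained by applying the joint
rotations about their *initial* axes distal-first:

    p_world = T_neck( T_hs( T_sp(p_0) ) )

which is the standard product-of-exponentials form of a serial chain with
axes given in the reference configuration.

All joints are abstracted as velocity-controlled servo motors: the angular
velocity is proportional to the error between the CPG drive signal (target
angle) and the current angle, clamped at a maximum rate that stands in for
the motor torque limit.  Masses are retained as metadata only; with the
default gain the tracking error against the CPG target is bounded well
below the joint working ranges (HS <= 1.5 deg RMSE on the standard run),
which is the contract the full dynamics simulation satisfied.

Units: positions in meters, segment lengths in millimeters, angles in
degrees at API boundaries (radians only inside rotation math).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .rhythm_core import OSCILLATOR_NAMES, NetworkSpec, simulate_network

__all__ = [
    "JointSpec",
    "SegmentSpec",
    "ServoConfig",
    "Pose",
    "KinematicChain",
    "TrialResult",
    "forward_kinematics",
    "tip_trajectories",
    "servo_step",
    "servo_track",
    "simulate_trial",
]

_DEG = np.pi / 180.0


@dataclass(frozen=True)
class JointSpec:
    """Hinge joint: pivot position (m) and unit rotation axis in the
    external frame at the initial posture."""

    name: str
    side: str  # "left" | "right" | "center"
    pivot: np.ndarray
    axis: np.ndarray

    def __post_init__(self) -> None:
        pivot = np.asarray(self.pivot, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        if pivot.shape != (3,) or axis.shape != (3,):
            raise ValueError("pivot and axis must be 3-vectors")
        norm = np.linalg.norm(axis)
        if abs(norm - 1.0) > 1e-6:
            axis = axis / norm
        object.__setattr__(self, "pivot", pivot)
        object.__setattr__(self, "axis", axis)

    def mirrored(self) -> "JointSpec":
        """Mirror image across the sagittal plane y = 0.

        The pivot's y coordinate and the axis's y component are negated;
        the hinge sense is kept, so mirrored *postures* correspond to
        sign-inverted joint angles (matching the sign inversion of the
        right-antenna offsets).
        """
        side = {"left": "right", "right": "left"}.get(self.side, self.side)
        return replace(
            self,
            side=side,
            pivot=self.pivot * np.array([1.0, -1.0, 1.0]),
            axis=self.axis * np.array([1.0, -1.0, 1.0]),
        )


@dataclass(frozen=True)
class SegmentSpec:
    """Rigid segment; mass is configuration metadata only (the joints are
    kinematic servos, not torque-driven bodies)."""

    name: str
    length_mm: float
    mass_mg: float

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("segment length must be positive")

    @property
    def length_m(self) -> float:
        return self.length_mm / 1000.0


@dataclass(frozen=True)
class ServoConfig:
    """Proportional velocity servo: rate = clamp(K*(target-current))."""

    K: float = 380.0  # proportional gain, 1/s
    max_rate: float = 2000.0  # deg/s; stands in for the torque limit

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("servo gain K must be positive")
        if self.max_rate <= 0:
            raise ValueError("max_rate must be positive")


@dataclass(frozen=True)
class Pose:
    """Joint angles in degrees relative to the initial posture."""

    neck: float = 0.0
    hs_left: float = 0.0
    sp_left: float = 0.0
    hs_right: float = 0.0
    sp_right: float = 0.0

    def as_array(self) -> np.ndarray:
        """Canonical oscillator ordering (sp_l, hs_l, neck, hs_r, sp_r)."""
        return np.array(
            [self.sp_left, self.hs_left, self.neck, self.hs_right, self.sp_right]
        )

    @classmethod
    def from_array(cls, arr) -> "Pose":
        sp_l, hs_l, neck, hs_r, sp_r = np.asarray(arr, dtype=float)
        return cls(neck=neck, hs_left=hs_l, sp_left=sp_l, hs_right=hs_r, sp_right=sp_r)


@dataclass(frozen=True)
class KinematicChain:
    """Geometry of the head-antenna system (left side + mirror)."""

    neck: JointSpec
    hs_left: JointSpec
    sp_left: JointSpec
    scape: SegmentSpec
    pedicel_flagellum: SegmentSpec
    head_diameter_mm: float
    head_mass_mg: float
    antenna_angle_deg: float = 10.0  # initial medial angle of the antennae

    def __post_init__(self) -> None:
        # scape length must be consistent with the pivot separation (1%)
        d = np.linalg.norm(self.sp_left.pivot - self.hs_left.pivot)
        if not np.isclose(d * 1000.0, self.scape.length_mm, rtol=0.012):
            raise ValueError(
                f"HS-SP pivot distance {d*1000.0:.2f} mm inconsistent with "
                f"scape length {self.scape.length_mm} mm"
            )

    @property
    def hs_right(self) -> JointSpec:
        return self.hs_left.mirrored()

    @property
    def sp_right(self) -> JointSpec:
        return self.sp_left.mirrored()

    def distal_direction(self, side: str) -> np.ndarray:
        """Unit direction of the pedicel-flagellum at the initial posture:
        horizontal, rotated ``antenna_angle_deg`` medially from straight
        ahead."""
        ang = self.antenna_angle_deg * _DEG
        sy = 1.0 if side == "left" else -1.0  # medial = +y on the left
        return np.array([np.cos(ang), sy * np.sin(ang), 0.0])

    @classmethod
    def default(cls) -> "KinematicChain":
        return cls(
            neck=JointSpec("neck", "center", (-0.015, 0.0, 0.0), (0.0, 0.0, 1.0)),
            hs_left=JointSpec(
                "HS", "left", (0.0174, -0.0083, 0.0100), (-0.1480, 0.8430, 0.5140)
            ),
            sp_left=JointSpec(
                "SP", "left", (0.0342, -0.0066, 0.0100), (-0.1530, 0.8690, -0.4690)
            ),
            scape=SegmentSpec("scape", 17.0, 3.0),
            pedicel_flagellum=SegmentSpec("pedicel_flagellum", 263.0, 12.5),
            head_diameter_mm=40.0,
            head_mass_mg=200.0,
        )


# ---------------------------------------------------------------------------
# forward kinematics


def _rotate_about(
    points: np.ndarray, joint: JointSpec, angles_deg: np.ndarray
) -> np.ndarray:
    """Rotate points (N,3) about a joint's initial axis through its pivot."""
    rot = Rotation.from_rotvec(np.multiply.outer(angles_deg * _DEG, joint.axis))
    return joint.pivot + rot.apply(points - joint.pivot)


def _side_tips(
    angles: dict, chain: KinematicChain, side: str
) -> tuple[np.ndarray, np.ndarray]:
    hs = chain.hs_left if side == "left" else chain.hs_right
    sp = chain.sp_left if side == "left" else chain.sp_right
    tip0 = sp.pivot + chain.pedicel_flagellum.length_m * chain.distal_direction(side)
    n = len(angles["neck"])
    tips = np.broadcast_to(tip0, (n, 3)).copy()
    pivots = np.broadcast_to(sp.pivot, (n, 3)).copy()
    # distal-first composition about the initial axes
    tips = _rotate_about(tips, sp, angles["sp_" + side])
    for pts in (tips, pivots):
        pts[:] = _rotate_about(pts, hs, angles["hs_" + side])
        pts[:] = _rotate_about(pts, chain.neck, angles["neck"])
    return tips, pivots


def tip_trajectories(
    angles: np.ndarray, chain: KinematicChain | None = None, return_pivots: bool = False
):
    """Antennal tip positions for a sequence of poses.

    Parameters
    ----------
    angles : ndarray, shape (N, 5)
        Joint angles in degrees, canonical order
        (sp_left, hs_left, neck, hs_right, sp_right).

    Returns
    -------
    (tips_left, tips_right) : ndarray (N, 3) each, meters.  With
    ``return_pivots=True`` the transformed SP pivot positions are appended.
    """
    if chain is None:
        chain = KinematicChain.default()
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    if angles.shape[1] != 5:
        raise ValueError("angles must have 5 columns (canonical order)")
    if not np.all(np.isfinite(angles)):
        raise ValueError("non-finite joint angles")
    named = {name: angles[:, k] for k, name in enumerate(OSCILLATOR_NAMES)}
    tips_l, piv_l = _side_tips(named, chain, "left")
    tips_r, piv_r = _side_tips(named, chain, "right")
    if return_pivots:
        return tips_l, tips_r, piv_l, piv_r
    return tips_l, tips_r


def forward_kinematics(
    pose: Pose, chain: KinematicChain | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Antennal tip positions (left, right) in meters for a single pose."""
    tips_l, tips_r = tip_trajectories(pose.as_array()[None, :], chain)
    return tips_l[0], tips_r[0]


# ---------------------------------------------------------------------------
# servo joints


def servo_step(
    current_angle, target_angle, config: ServoConfig, dt: float
):
    """One explicit-Euler step of the proportional velocity servo.

    ``next = current + clamp(K*(target-current), +/-max_rate) * dt``;
    works element-wise on arrays.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    err = np.asarray(target_angle, dtype=float) - np.asarray(current_angle, dtype=float)
    vel = np.clip(config.K * err, -config.max_rate, config.max_rate)
    out = current_angle + vel * dt
    return float(out) if np.ndim(out) == 0 else out


def servo_track(
    targets: np.ndarray, config: ServoConfig, dt: float, initial: np.ndarray | None = None
) -> np.ndarray:
    """Run the servo over a target sequence (steps along axis 0)."""
    targets = np.asarray(targets, dtype=float)
    out = np.empty_like(targets)
    out[0] = targets[0] if initial is None else initial
    for k in range(1, len(targets)):
        out[k] = servo_step(out[k - 1], targets[k - 1], config, dt)
    return out


# ---------------------------------------------------------------------------
# full trial simulation


@dataclass
class TrialResult:
    """Joint-angle traces and tip trajectories of one simulated trial,
    resampled to the experimental 50 Hz convention; the integration
    transient has been discarded.

    ``targets`` are the CPG drive signals x, ``angles`` the servo-attained
    joint angles (both degrees, canonical oscillator order); ``theta`` is
    the unwrapped oscillator phase (radians), available for in-model
    circular statistics.
    """

    time: np.ndarray
    targets: np.ndarray
    angles: np.ndarray
    theta: np.ndarray
    tips_left: np.ndarray
    tips_right: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def joint(self, name: str, attained: bool = True) -> np.ndarray:
        k = OSCILLATOR_NAMES.index(name)
        return (self.angles if attained else self.targets)[:, k]

    def tracking_rmse(self, name: str) -> float:
        """RMSE (deg) between CPG target and attained angle for a joint."""
        k = OSCILLATOR_NAMES.index(name)
        return float(np.sqrt(np.mean((self.targets[:, k] - self.angles[:, k]) ** 2)))

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_s": self.time}
        for k, name in enumerate(OSCILLATOR_NAMES):
            cols[f"angle_{name}_deg"] = self.angles[:, k]
        for k, name in enumerate(OSCILLATOR_NAMES):
            cols[f"target_{name}_deg"] = self.targets[:, k]
        for j, ax in enumerate("xyz"):
            cols[f"tip_left_{ax}_m"] = self.tips_left[:, j]
        for j, ax in enumerate("xyz"):
            cols[f"tip_right_{ax}_m"] = self.tips_right[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate_trial(
    spec: NetworkSpec,
    patterns,
    chain: KinematicChain | None = None,
    servo: ServoConfig | None = None,
    duration: float = 60.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    transient: float = 5.0,
    fs_out: float = 50.0,
) -> TrialResult:
    """Simulate a full tactile-exploration trial.

    The CPG is integrated at ``spec.dt`` (5 ms); at every step the servos
    track the drive signals; the transient is discarded and the result is
    resampled to ``fs_out`` (50 Hz) to match the experimental convention,
    after which the tip trajectories are evaluated.
    """
    if chain is None:
        chain = KinematicChain.default()
    if servo is None:
        servo = ServoConfig()
    if duration <= 0:
        raise ValueError("duration must be positive")
    step_ratio = 1.0 / (fs_out * spec.dt)
    q = int(round(step_ratio))
    if abs(step_ratio - q) > 1e-9 or q < 1:
        raise ValueError("1/(fs_out*dt) must be a positive integer")

    traj = simulate_network(spec, patterns, transient + duration, seed=seed, rng=rng)
    attained = servo_track(traj.x, servo, spec.dt)

    n_skip = int(round(transient / spec.dt))
    sl = slice(n_skip, None, q)
    time = traj.time[sl] - traj.time[n_skip]
    targets = traj.x[sl]
    angles = attained[sl]
    theta = traj.theta[sl]
    tips_l, tips_r = tip_trajectories(angles, chain)
    return TrialResult(
        time=time,
        targets=targets,
        angles=angles,
        theta=theta,
        tips_left=tips_l,
        tips_right=tips_r,
        fs=fs_out,
        meta={
            "duration": duration,
            "transient": transient,
            "dt": spec.dt,
            "seed": seed,
            "servo_K": servo.K,
            "servo_max_rate": servo.max_rate,
        },
    )
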