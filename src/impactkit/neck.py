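"""Two-linkage head-neck-torso kinematic model.

A head rigid body rides on a neck link through a universal joint whose
rotation axes are the head's left-right axis (atlanto-occipital
flexion/extension, angle ``theta_lr``) and inferior-superior axis
(atlanto-axial axial rotation, ``theta_is``).  The neck's base — its
attachment to the torso — is constrained to stay as close as possible to
its position at t = 0, encoding the assumption of a massive, nearly
stationary torso under a much lighter head.

Given the head's six degrees of freedom (orientation integrated from
angular velocity, centre-of-gravity position double-integrated from
CoG-transformed linear acceleration), the system is fully determined: two
universal-joint angles, three neck orientation angles, and the residual
base offset ``d``.

The base-offset minimisation has a closed form.  Writing the neck axis in
the head frame as u(theta_lr, theta_is), the base is
B = J - L * R_head @ u, and |B - B0| is minimised over the unit sphere by
aligning u with the head-frame direction of (J - B0); then
d = | |J - B0| - L |.  Samples whose optimal axis leaves the
(-pi/2, pi/2) joint branch are flagged and carried from the previous
sample.

Gravity is not modelled, consistent with the preprocessing chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .io import DT_S, GRAVITY, N_SAMPLES
from .preprocess import AnatomicalSignals, cumulative_trapezoid_integral, five_point_derivative
from .registry import ANGLE_NAMES, POINT_NAMES, RATIO_PAIRS

#: deadband below which a joint angle counts as matching either sign (rad)
SIGNMATCH_DEADBAND_RAD = 1e-3
#: linear-acceleration denominator deadband for coupling ratios (g)
RATIO_DEADBAND_G = 0.5


@dataclass
class NeckModelParams:
    """Link lengths and the sensor-to-CoG lever arm (metres)."""

    neck_length: float = 0.108          # torso base to head-neck joint
    cog_height: float = 0.05            # head-neck joint to head CoG
    lever_arm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.lever_arm = np.asarray(self.lever_arm, dtype=float)
        if self.neck_length <= 0 or self.cog_height <= 0:
            raise ValueError("link lengths must be positive")


@dataclass
class HeadTrajectory:
    """Integrated head pose over the 100 ms window."""

    orientations: np.ndarray   # (N, 3, 3), world-from-head
    cog_pos: np.ndarray        # (3, N), m, world frame, origin at t=0
    cog_vel: np.ndarray        # (3, N), m/s
    cog_acc: np.ndarray        # (3, N), m/s^2


@dataclass
class NeckModelTrajectory:
    """Per-sample linkage solution."""

    theta_lr: np.ndarray       # (N,), rad, atlanto-occipital
    theta_is: np.ndarray       # (N,), rad, atlanto-axial
    neck_angles: np.ndarray    # (3, N), rad, neck orientation about AP/LR/IS
    base_pos: np.ndarray       # (3, N), m
    head_base: np.ndarray      # (3, N), m
    head_cog: np.ndarray       # (3, N), m
    d: np.ndarray              # (N,), m, base offset from its t=0 position
    flagged: np.ndarray        # (N,), bool, carried-over samples
    params: NeckModelParams


def transform_acc_to_cog(sig: AnatomicalSignals,
                         params: NeckModelParams) -> np.ndarray:
    """Rigid-body transform of linear acceleration to the head CoG (in g).

    a_cog = a_sensor + alpha x r + omega x (omega x r), with the angular
    acceleration alpha from the five-point stencil of angular velocity.
    """
    r = params.lever_arm
    if not r.any():
        return sig.lin_acc.copy()
    omega = sig.ang_vel.T                       # (N, 3)
    alpha = five_point_derivative(sig.ang_vel, sig.dt).T
    extra = np.cross(alpha, r) + np.cross(omega, np.cross(omega, r))
    return sig.lin_acc + extra.T / GRAVITY


def integrate_head_pose(sig: AnatomicalSignals,
                        params: NeckModelParams) -> HeadTrajectory:
    """Integrate orientation (exponential map) and CoG position (trapezoid).

    Initial conditions: identity orientation, zero velocity, CoG at the
    origin.  Orientation steps use the midpoint body-frame angular
    velocity: R[k+1] = R[k] @ Exp(dt * (w[k] + w[k+1]) / 2).
    """
    n = sig.ang_vel.shape[1]
    R = np.empty((n, 3, 3))
    R[0] = np.eye(3)
    w = sig.ang_vel
    for k in range(n - 1):
        step = Rotation.from_rotvec(0.5 * (w[:, k] + w[:, k + 1]) * sig.dt)
        R[k + 1] = R[k] @ step.as_matrix()
    a_body = transform_acc_to_cog(sig, params) * GRAVITY   # m/s^2, head frame
    a_world = np.einsum("nij,jn->in", R, a_body)
    vel = cumulative_trapezoid_integral(a_world, sig.dt)
    pos = cumulative_trapezoid_integral(vel, sig.dt)
    return HeadTrajectory(orientations=R, cog_pos=pos, cog_vel=vel, cog_acc=a_world)


def _angles_from_axis(u: np.ndarray) -> tuple[float, float] | None:
    """Recover (theta_lr, theta_is) from the head-frame neck axis.

    u = (-sin t1 cos t2, sin t1 sin t2, cos t1); both angles restricted to
    the (-pi/2, pi/2) branch.  Returns None when u leaves the branch
    (u_z <= 0).
    """
    ux, uy, uz = u
    if uz <= 0:
        return None
    s1 = float(np.hypot(ux, uy))
    if s1 < 1e-15:
        return 0.0, 0.0
    t2 = float(np.arctan2(uy, -ux))
    if abs(t2) > np.pi / 2:
        s1, t2 = -s1, t2 - np.sign(t2) * np.pi
    return float(np.arctan2(s1, uz)), t2


def _universal_joint(theta_lr: float, theta_is: float) -> np.ndarray:
    """Joint rotation: about LR (y) then about IS (z)."""
    cy, sy = np.cos(theta_lr), np.sin(theta_lr)
    cz, sz = np.cos(theta_is), np.sin(theta_is)
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Ry @ Rz


def solve_linkage(traj: HeadTrajectory,
                  params: NeckModelParams) -> NeckModelTrajectory:
    """Solve joint angles, neck orientation, base position, and offset d."""
    n = traj.orientations.shape[0]
    h, L = params.cog_height, params.neck_length
    e3 = np.array([0.0, 0.0, 1.0])
    # head-base (joint) point: CoG sits cog_height above it along head +IS
    J = traj.cog_pos - np.einsum("nij,j->in", traj.orientations, h * e3)
    # neutral base: neck aligned with the head's initial IS axis
    B0 = J[:, 0] - L * traj.orientations[0] @ e3

    theta_lr = np.zeros(n)
    theta_is = np.zeros(n)
    neck_angles = np.zeros((3, n))
    base = np.zeros((3, n))
    d = np.zeros(n)
    flagged = np.zeros(n, dtype=bool)
    prev = (0.0, 0.0)
    for k in range(n):
        Rk = traj.orientations[k]
        v = J[:, k] - B0
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            angles = prev
            vhat = Rk @ _universal_joint(*angles).T @ e3
        else:
            vhat = v / nv
            angles = _angles_from_axis(Rk.T @ vhat)
            if angles is None:
                flagged[k] = True
                angles = prev
                vhat = Rk @ _universal_joint(*angles).T @ e3
        theta_lr[k], theta_is[k] = angles
        prev = angles
        R_neck = Rk @ _universal_joint(*angles).T
        neck_angles[:, k] = Rotation.from_matrix(R_neck).as_euler("xyz")
        base[:, k] = J[:, k] - L * vhat
        d[k] = np.linalg.norm(base[:, k] - B0)
    return NeckModelTrajectory(
        theta_lr=theta_lr, theta_is=theta_is, neck_angles=neck_angles,
        base_pos=base, head_base=J, head_cog=traj.cog_pos, d=d,
        flagged=flagged, params=params)


def _signmatch_percent(a: np.ndarray, b: np.ndarray,
                       deadband: float = SIGNMATCH_DEADBAND_RAD) -> float:
    """Percent of samples where the two angle series agree in sign.

    Angles inside the deadband match either sign, so a stationary
    trajectory scores 100 rather than being undefined.
    """
    small = (np.abs(a) < deadband) | (np.abs(b) < deadband)
    match = small | (np.sign(a) == np.sign(b))
    return 100.0 * float(np.mean(match))


def model_features(nmt: NeckModelTrajectory, dt: float = DT_S) -> dict[str, float]:
    """The 33 non-ratio model-block features."""
    out: dict[str, float] = {
        "nm_signmatch_lr": _signmatch_percent(nmt.theta_lr, nmt.neck_angles[1]),
        "nm_signmatch_is": _signmatch_percent(nmt.theta_is, nmt.neck_angles[2]),
    }
    angle_series = {
        "uj_lr": nmt.theta_lr, "uj_is": nmt.theta_is,
        "neck_ap": nmt.neck_angles[0], "neck_lr": nmt.neck_angles[1],
        "neck_is": nmt.neck_angles[2],
    }
    for name in ANGLE_NAMES:
        s = angle_series[name]
        vel = five_point_derivative(s, dt)
        acc = five_point_derivative(vel, dt)
        out[f"nm_peak_angle_{name}"] = float(np.abs(s).max())
        out[f"nm_peak_angvel_{name}"] = float(np.abs(vel).max())
        out[f"nm_peak_angacc_{name}"] = float(np.abs(acc).max())
    points = {"torso_base": nmt.base_pos, "head_base": nmt.head_base,
              "head_cog": nmt.head_cog}
    for name in POINT_NAMES:
        p = points[name]
        disp = p - p[:, [0]]
        vel = five_point_derivative(p, dt)
        acc = five_point_derivative(vel, dt)
        out[f"nm_peak_disp_{name}"] = float(np.linalg.norm(disp, axis=0).max())
        out[f"nm_peak_vel_{name}"] = float(np.linalg.norm(vel, axis=0).max())
        out[f"nm_peak_acc_{name}"] = float(np.linalg.norm(acc, axis=0).max())
    cog_disp = nmt.head_cog - nmt.head_cog[:, [0]]
    cog_vel = five_point_derivative(nmt.head_cog, dt)
    for i, ax in enumerate(("ap", "lr", "is")):
        out[f"nm_peak_disp_cog_{ax}"] = float(np.abs(cog_disp[i]).max())
        out[f"nm_peak_vel_cog_{ax}"] = float(np.abs(cog_vel[i]).max())
    out["nm_peak_base_offset"] = float(nmt.d.max())
    return out


def coupling_ratios(sig: AnatomicalSignals) -> dict[str, float]:
    """Head-neck coupling ratios: angular acceleration about each axis over
    linear acceleration along each normal axis (18 features).

    Each of the six ratio series is evaluated per sample where the linear-
    acceleration denominator exceeds the 0.5 g deadband; the mean, standard
    deviation, and peak |ratio| of each series are the features.  A series
    with no retained samples contributes three zeros.
    """
    lin = {"ap": sig.lin_acc[0], "lr": sig.lin_acc[1], "is": sig.lin_acc[2]}
    ang = {"cor": sig.ang_acc[0], "sag": sig.ang_acc[1], "hor": sig.ang_acc[2]}
    out: dict[str, float] = {}
    for plane, axis in RATIO_PAIRS:
        denom = lin[axis]
        keep = np.abs(denom) >= RATIO_DEADBAND_G
        base = f"cr_{plane}_{axis}"
        if not keep.any():
            out[f"{base}_mean"] = out[f"{base}_std"] = out[f"{base}_peak"] = 0.0
            continue
        ratio = ang[plane][keep] / denom[keep]
        out[f"{base}_mean"] = float(ratio.mean())
        out[f"{base}_std"] = float(ratio.std())
        out[f"{base}_peak"] = float(np.abs(ratio).max())
    return out


def model_feature_block(sig: AnatomicalSignals,
                        params: NeckModelParams | None = None) -> dict[str, float]:
    """Full 51-feature model block: linkage kinematics + coupling ratios."""
    params = params or NeckModelParams()
    traj = integrate_head_pose(sig, params)
    nmt = solve_linkage(traj, params)
    out = model_features(nmt, sig.dt)
    out.update(coupling_ratios(sig))
    return out
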