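"""Serial six-revolute-joint chain kinematics.

The wearable brace is modelled as a serial chain of six revolute joints in
the standard (distal) Denavit-Hartenberg convention, transform order
``Rot_z(theta) . Trans_z(d) . Trans_x(a) . Rot_x(alpha)`` per joint.  The
structure mirrors head-neck biomechanics:

* joints 1 and 2 have parallel axes (sagittal-plane linkage),
* joints 3 and 4 are perpendicular to them (lateral bending),
* joints 4, 5 and 6 are concurrent at a point ``C`` that mimics a ball
  joint near the atlanto-axial level; the end-effector ``P`` sits on the
  top of the head.

All internal angles are radians and lengths millimetres; public
"anatomical" head angles are degrees.  The base frame sits at the C7
mount with ``x`` anterior, ``y`` toward the subject's left and ``z`` up.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .errors import InvalidInputError

__all__ = [
    "ANGLE_NAMES",
    "DHChain",
    "Pose",
    "HeadAngles",
    "IKResult",
    "forward_kinematics",
    "forward_kinematics_batch",
    "point_on_chain",
    "point_on_chain_batch",
    "inverse_kinematics",
    "ik_trajectory",
    "compose_head_angles",
    "head_angles_from_pose",
    "head_angles_from_matrices",
    "default_chain",
    "load_chain",
    "save_chain",
]

#: order of the anatomical angle triplet everywhere in this package
ANGLE_NAMES = ("flexion_extension", "lateral_bending", "axial_rotation")

#: orientation error (rad) is scaled to millimetres by this length so the
#: 6-vector pose error used by the IK solver is homogeneous.
CHARACTERISTIC_LENGTH_MM = 100.0

# Intrinsic Euler sequence for head angles: vertical (Z) -> anteroposterior
# (X) -> mediolateral (Y).  Sign conventions: positive flexion_extension is
# extension, positive lateral_bending and axial_rotation are toward the
# subject's right.  With x anterior / y left / z up this requires the sign
# flips below (rotation toward the right is negative about +z, extension is
# negative about +y).
_EULER_SEQ = "ZXY"
# euler order (Z, X, Y) -> (axial, lateral, flexext); signs applied on both
# composition and decomposition.
_EULER_SIGNS = np.array([-1.0, 1.0, -1.0])

_GIMBAL_GUARD_DEG = 0.5


# ---------------------------------------------------------------------------
# basic types
# ---------------------------------------------------------------------------


def _check_rotation(R: np.ndarray, tol: float = 1e-9) -> None:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidInputError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R @ R.T, np.eye(3), atol=tol):
        raise InvalidInputError("rotation matrix is not orthonormal")
    if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-6):
        raise InvalidInputError("rotation matrix must be proper (det +1)")


@dataclass(frozen=True)
class Pose:
    """Rigid pose: position in mm plus a proper orthonormal rotation."""

    position: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float).reshape(3)
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.all(np.isfinite(p)):
            raise InvalidInputError("pose position must be finite")
        _check_rotation(R)
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "rotation", R)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.zeros(3), np.eye(3))

    @classmethod
    def from_matrix(cls, T: np.ndarray) -> "Pose":
        T = np.asarray(T, dtype=float)
        return cls(T[:3, 3], T[:3, :3])

    @property
    def matrix(self) -> np.ndarray:
        T = np.eye(4)
        T[:3, :3] = self.rotation
        T[:3, 3] = self.position
        return T

    def inverse(self) -> "Pose":
        R = self.rotation.T
        return Pose(-R @ self.position, R)

    def transform_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.position


@dataclass(frozen=True)
class HeadAngles:
    """Anatomical head angles in degrees.

    Positive flexion_extension is extension; positive lateral_bending and
    axial_rotation are toward the subject's right (dissected side in the
    clinical protocol).
    """

    flexion_extension: float
    lateral_bending: float
    axial_rotation: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.flexion_extension, self.lateral_bending, self.axial_rotation]
        )


@dataclass
class IKResult:
    q: np.ndarray
    converged: bool
    position_residual_mm: float
    orientation_residual_deg: float


# ---------------------------------------------------------------------------
# chain definition
# ---------------------------------------------------------------------------


@dataclass
class DHChain:
    """Six-revolute chain in standard DH convention.

    ``a`` (mm), ``alpha`` (rad), ``d`` (mm) and ``theta0`` (rad) are the
    per-joint constants; the joint variable ``q_i`` adds to ``theta0_i``.
    ``base`` and ``tool`` are fixed poses bracketing the chain so the base
    frame can be anatomically aligned and the neutral end-effector
    orientation can be made the identity.
    """

    a: np.ndarray
    alpha: np.ndarray
    d: np.ndarray
    theta0: np.ndarray
    joint_limits: np.ndarray  # (6, 2) rad
    base: Pose = field(default_factory=Pose.identity)
    tool: Pose = field(default_factory=Pose.identity)
    labels: Sequence[str] = ("J1", "J2", "J3", "J4", "J5", "J6")

    def __post_init__(self) -> None:
        for name in ("a", "alpha", "d", "theta0"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(-1)
            if v.size != 6 or not np.all(np.isfinite(v)):
                raise InvalidInputError(f"{name} must be 6 finite values")
            setattr(self, name, v)
        lim = np.asarray(self.joint_limits, dtype=float).reshape(6, 2)
        if np.any(lim[:, 0] >= lim[:, 1]):
            raise InvalidInputError("joint limits must satisfy min < max")
        self.joint_limits = lim
        # fixed per-joint tail transform Trans_z(d) Trans_x(a) Rot_x(alpha)
        tails = np.zeros((6, 4, 4))
        for i in range(6):
            ca, sa = math.cos(self.alpha[i]), math.sin(self.alpha[i])
            tails[i] = np.array(
                [
                    [1.0, 0.0, 0.0, self.a[i]],
                    [0.0, ca, -sa, 0.0],
                    [0.0, sa, ca, 0.0],
                    [0.0, 0.0, 0.0, 1.0],
                ]
            )
            tails[i][2, 3] = self.d[i]
            # careful: order is Trans_z(d) then Trans_x(a) then Rot_x(alpha);
            # translation column is (a, 0, d) in the local frame.
            tails[i][0, 3] = self.a[i]
            tails[i][1, 3] = 0.0
            tails[i][2, 3] = self.d[i]
        self._tails = tails

    # -- structure ---------------------------------------------------------

    @property
    def neutral_q(self) -> np.ndarray:
        return np.zeros(6)

    def total_link_length(self) -> float:
        """Sum of |a| + |d|, used as a compactness ranking in design search."""
        return float(np.sum(np.abs(self.a)) + np.sum(np.abs(self.d)))

    def clamp(self, q: np.ndarray) -> np.ndarray:
        return np.clip(q, self.joint_limits[:, 0], self.joint_limits[:, 1])

    def within_limits(self, q: np.ndarray, tol: float = 1e-9) -> bool:
        q = np.asarray(q, dtype=float)
        return bool(
            np.all(q >= self.joint_limits[:, 0] - tol)
            and np.all(q <= self.joint_limits[:, 1] + tol)
        )

    def joint_axes_and_origins(self, q: np.ndarray):
        """Base-frame joint axis directions ``z_i`` and origins ``o_i``.

        Joint ``i`` (1-based) rotates about axis ``z[i-1]`` through
        ``o[i-1]``.
        """
        origins, axes, _ = _fk_frames(self, np.asarray(q, dtype=float)[None, :])
        return axes[0], origins[0]

    def validate_structure(self) -> None:
        """Check the design axis constraints at the neutral configuration.

        Raises :class:`InvalidInputError` if J1/J2 axes are not parallel,
        J3/J4 axes are not perpendicular to them, or the distal three axes
        are not concurrent.
        """
        z, o = self.joint_axes_and_origins(self.neutral_q)
        if abs(abs(float(z[0] @ z[1])) - 1.0) > 1e-9:
            raise InvalidInputError("axes of J1 and J2 must be parallel")
        for j in (2, 3):
            if abs(float(z[0] @ z[j])) > 1e-9:
                raise InvalidInputError(
                    f"axis of J{j + 1} must be perpendicular to J1/J2"
                )
        lines = [(o[j], z[j]) for j in (3, 4, 5)]
        for i in range(3):
            for j in range(i + 1, 3):
                if _line_distance(*lines[i], *lines[j]) > 1e-6:
                    raise InvalidInputError(
                        "axes of J4, J5, J6 must be concurrent at C"
                    )

    def concurrency_point(self, q: np.ndarray) -> np.ndarray:
        """Point ``C`` where the distal three joint axes intersect."""
        return point_on_chain(self, q, 5)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "joints": [
                {
                    "label": self.labels[i],
                    "a_mm": float(self.a[i]),
                    "alpha_deg": math.degrees(self.alpha[i]),
                    "d_mm": float(self.d[i]),
                    "theta0_deg": math.degrees(self.theta0[i]),
                    "limits_deg": [
                        math.degrees(self.joint_limits[i, 0]),
                        math.degrees(self.joint_limits[i, 1]),
                    ],
                }
                for i in range(6)
            ],
            "base": {
                "position_mm": self.base.position.tolist(),
                "rotation": self.base.rotation.tolist(),
            },
            "tool": {
                "position_mm": self.tool.position.tolist(),
                "rotation": self.tool.rotation.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DHChain":
        joints = data["joints"]
        if len(joints) != 6:
            raise InvalidInputError("chain definition must have 6 joints")
        a = [j["a_mm"] for j in joints]
        alpha = [math.radians(j["alpha_deg"]) for j in joints]
        d = [j["d_mm"] for j in joints]
        theta0 = [math.radians(j["theta0_deg"]) for j in joints]
        limits = [
            [math.radians(j["limits_deg"][0]), math.radians(j["limits_deg"][1])]
            for j in joints
        ]
        labels = tuple(j.get("label", f"J{i + 1}") for i, j in enumerate(joints))
        base = Pose.identity()
        tool = Pose.identity()
        if "base" in data:
            base = Pose(np.array(data["base"]["position_mm"]),
                        np.array(data["base"]["rotation"]))
        if "tool" in data:
            tool = Pose(np.array(data["tool"]["position_mm"]),
                        np.array(data["tool"]["rotation"]))
        return cls(a, alpha, d, theta0, limits, base=base, tool=tool,
                   labels=labels)

    def with_params(self, a=None, d=None) -> "DHChain":
        """Copy of the chain with some link lengths / offsets replaced."""
        return replace(
            self,
            a=self.a if a is None else np.asarray(a, dtype=float),
            d=self.d if d is None else np.asarray(d, dtype=float),
        )


def save_chain(chain: DHChain, path: str | Path) -> None:
    path = Path(path)
    data = chain.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_chain(path: str | Path) -> DHChain:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return DHChain.from_dict(data)


def _line_distance(p1, d1, p2, d2) -> float:
    """Common-perpendicular distance between two lines (mm)."""
    n = np.cross(d1, d2)
    nn = np.linalg.norm(n)
    if nn < 1e-12:  # parallel: distance of p2 from line 1
        v = p2 - p1
        return float(np.linalg.norm(v - (v @ d1) * d1 / (d1 @ d1)))
    return float(abs((p2 - p1) @ n) / nn)


# ---------------------------------------------------------------------------
# forward kinematics (batched over samples)
# ---------------------------------------------------------------------------


def _fk_frames(chain: DHChain, q: np.ndarray):
    """All intermediate frames for a batch of configurations.

    Parameters
    ----------
    q : (N, 6) array of joint angles (rad).

    Returns
    -------
    origins : (N, 7, 3) — origins o_0 .. o_6 (o_0 is the base origin, o_6 is
        the last DH frame origin before the tool transform).
    axes : (N, 7, 3) — z axes z_0 .. z_6 in the base frame.
    T_ee : (N, 4, 4) — end-effector transform including base and tool.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[1] != 6:
        raise InvalidInputError("q batch must have shape (N, 6)")
    if not np.all(np.isfinite(q)):
        raise InvalidInputError("joint angles must be finite")
    n = q.shape[0]
    T = np.broadcast_to(chain.base.matrix, (n, 4, 4)).copy()
    origins = np.empty((n, 7, 3))
    axes = np.empty((n, 7, 3))
    origins[:, 0] = T[:, :3, 3]
    axes[:, 0] = T[:, :3, 2]
    theta = q + chain.theta0
    rot = np.zeros((n, 4, 4))
    rot[:, 2, 2] = 1.0
    rot[:, 3, 3] = 1.0
    for i in range(6):
        c = np.cos(theta[:, i])
        s = np.sin(theta[:, i])
        rot[:, 0, 0] = c
        rot[:, 0, 1] = -s
        rot[:, 1, 0] = s
        rot[:, 1, 1] = c
        T = T @ rot @ chain._tails[i]
        origins[:, i + 1] = T[:, :3, 3]
        axes[:, i + 1] = T[:, :3, 2]
    T_ee = T @ chain.tool.matrix
    return origins, axes, T_ee


def forward_kinematics_batch(chain: DHChain, q: np.ndarray) -> np.ndarray:
    """End-effector transforms, shape (N, 4, 4), for a batch of q."""
    _, _, T = _fk_frames(chain, q)
    return T


def forward_kinematics(chain: DHChain, q: np.ndarray) -> Pose:
    """Pose of the end-effector ``P`` in the base (C7) frame."""
    q = np.asarray(q, dtype=float).reshape(-1)
    if q.size != 6:
        raise InvalidInputError("q must have 6 elements")
    T = forward_kinematics_batch(chain, q[None, :])[0]
    return Pose.from_matrix(T)


def point_on_chain_batch(chain: DHChain, q: np.ndarray, joint_index: int) -> np.ndarray:
    if not 1 <= joint_index <= 6:
        raise InvalidInputError(f"joint_index must be in 1..6, got {joint_index}")
    origins, _, _ = _fk_frames(chain, q)
    return origins[:, joint_index - 1]


def point_on_chain(chain: DHChain, q: np.ndarray, joint_index: int) -> np.ndarray:
    """Base-frame position (mm) of the origin of joint ``joint_index``."""
    q = np.asarray(q, dtype=float).reshape(-1)
    return point_on_chain_batch(chain, q[None, :], joint_index)[0]


# ---------------------------------------------------------------------------
# inverse kinematics: damped least squares, batched over targets
# ---------------------------------------------------------------------------


def _pose_error(T_now: np.ndarray, p_t: np.ndarray, R_t: np.ndarray):
    """Position (mm) and orientation (rotvec, rad) errors, batched."""
    e_pos = p_t - T_now[:, :3, 3]
    R_err = R_t @ np.swapaxes(T_now[:, :3, :3], 1, 2)
    w = Rotation.from_matrix(R_err).as_rotvec()
    if w.ndim == 1:
        w = w[None, :]
    return e_pos, w


def _ik_batch(
    chain: DHChain,
    targets: np.ndarray,
    q0: np.ndarray,
    *,
    position_only: bool = False,
    pos_tol: float = 1e-7,
    rot_tol: float = 1e-9,
    max_iter: int = 200,
    lam0: float = 1e-3,
):
    """Damped least-squares IK for a batch of pose targets.

    Orientation error (rad) is scaled by :data:`CHARACTERISTIC_LENGTH_MM`
    so it is commensurate with position error in mm.  Joint limits are
    enforced by projection after every step; damping adapts per target.
    """
    targets = np.asarray(targets, dtype=float)
    p_t = targets[:, :3, 3]
    R_t = targets[:, :3, :3]
    n = targets.shape[0]
    q = np.asarray(q0, dtype=float).copy()
    if q.ndim == 1:
        q = np.broadcast_to(q, (n, 6)).copy()
    q = np.clip(q, chain.joint_limits[:, 0], chain.joint_limits[:, 1])
    lam = np.full(n, lam0)
    L = CHARACTERISTIC_LENGTH_MM
    ndim = 3 if position_only else 6

    origins, axes, T = _fk_frames(chain, q)
    e_pos, e_rot = _pose_error(T, p_t, R_t)
    err = e_pos if position_only else np.concatenate([e_pos, L * e_rot], axis=1)
    err_norm = np.linalg.norm(err, axis=1)

    eye = np.eye(6)
    for _ in range(max_iter):
        pos_ok = np.linalg.norm(e_pos, axis=1) <= pos_tol
        rot_ok = (
            np.ones(n, dtype=bool)
            if position_only
            else np.linalg.norm(e_rot, axis=1) <= rot_tol
        )
        active = ~(pos_ok & rot_ok)
        if not np.any(active):
            break
        idx = np.flatnonzero(active)
        # geometric Jacobian for active targets
        z = axes[idx, :6]  # (m, 6, 3) joint axes
        o = origins[idx, :6]
        p_now = T[idx, :3, 3]
        Jv = np.cross(z, (p_now[:, None, :] - o))  # (m, 6, 3)
        if position_only:
            J = np.swapaxes(Jv, 1, 2)  # (m, 3, 6)
        else:
            J = np.concatenate(
                [np.swapaxes(Jv, 1, 2), L * np.swapaxes(z, 1, 2)], axis=1
            )  # (m, 6, 6)
        e = err[idx, :ndim]
        JT = np.swapaxes(J, 1, 2)
        A = JT @ J + (lam[idx] ** 2)[:, None, None] * eye
        b = JT @ e[:, :, None]
        dq = np.linalg.solve(A, b)[:, :, 0]
        q_try = np.clip(
            q[idx] + dq, chain.joint_limits[:, 0], chain.joint_limits[:, 1]
        )
        o_try, z_try, T_try = _fk_frames(chain, q_try)
        ep_try, er_try = _pose_error(T_try, p_t[idx], R_t[idx])
        err_try = (
            ep_try
            if position_only
            else np.concatenate([ep_try, L * er_try], axis=1)
        )
        norm_try = np.linalg.norm(err_try, axis=1)
        better = norm_try <= err_norm[idx]
        acc = idx[better]
        q[acc] = q_try[better]
        origins[acc] = o_try[better]
        axes[acc] = z_try[better]
        T[acc] = T_try[better]
        e_pos[acc] = ep_try[better]
        if not position_only:
            e_rot[acc] = er_try[better]
        err[acc, :ndim] = err_try[better]
        err_norm[acc] = norm_try[better]
        lam[acc] = np.maximum(lam[acc] * 0.5, 1e-4)
        lam[idx[~better]] = np.minimum(lam[idx[~better]] * 10.0, 1e6)

    pos_res = np.linalg.norm(e_pos, axis=1)
    rot_res = (
        np.zeros(n) if position_only else np.linalg.norm(e_rot, axis=1)
    )
    # convergence reported against the practical pose tolerances
    converged = (pos_res <= 0.5) & (rot_res <= math.radians(0.05))
    return q, converged, pos_res, rot_res


def _has_decoupled_wrist(chain: DHChain) -> bool:
    """True if the chain matches the planar-pair + spherical-wrist layout.

    Pattern: twists (0, +90, -90, +90, -90, 0) deg, ``a3..a6 = 0`` and
    ``d1 = d2 = d5 = 0``.  The shipped default chain and every candidate
    produced by the design search have this structure, which admits a
    closed-form IK (wrist centre -> planar two-link -> ZYZ wrist).
    """
    h = math.pi / 2
    return (
        np.allclose(chain.alpha, [0.0, h, -h, h, -h, 0.0], atol=1e-12)
        and np.allclose(chain.a[2:], 0.0, atol=1e-12)
        and np.allclose(chain.d[[0, 1, 4]], 0.0, atol=1e-12)
    )


def _wrap_pi(x: np.ndarray) -> np.ndarray:
    return (x + math.pi) % (2.0 * math.pi) - math.pi


def _ik_analytic_candidates(chain: DHChain, targets: np.ndarray):
    """All closed-form IK branches for a decoupled-wrist chain.

    Returns ``(q_cand, valid)`` with shapes (N, 8, 6) and (N, 8); invalid
    branches (unreachable wrist centre / elbow triangle) are masked out.
    Candidates are expressed as joint variables (theta0 subtracted) wrapped
    into the representative closest to the joint-limit interval.
    """
    targets = np.asarray(targets, dtype=float)
    n = targets.shape[0]
    a1, a2 = chain.a[0], chain.a[1]
    d3, d4, d6 = chain.d[2], chain.d[3], chain.d[5]
    Rb, pb = chain.base.rotation, chain.base.position
    Rtl = chain.tool.rotation

    # targets in DH frame 0, tool removed
    p0 = (targets[:, :3, 3] - pb) @ Rb
    R0 = np.einsum("ij,njk,lk->nil", Rb.T, targets[:, :3, :3], Rtl)

    # wrist centre: frame-6 origin is C + d6 * z5, i.e. C = p - R0 @ (0,0,d6)
    Cw = p0 - d6 * R0[:, :, 2]

    q_cand = np.full((n, 8, 6), np.nan)
    valid = np.zeros((n, 8), dtype=bool)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.clip(Cw[:, 2] / d4, -1.5, 1.5)
        reach_t3 = np.abs(ratio) <= 1.0
        t3a = np.arccos(np.clip(ratio, -1.0, 1.0))
        for i3, t3 in enumerate((t3a, -t3a)):
            s3 = np.sin(t3)
            # remaining planar problem: Rz(t1) @ (a1,0) + Rz(phi) @ w = Cxy
            wx = a2 - d4 * s3
            wy = np.full(n, -d3)
            lw = np.hypot(wx, wy)
            px, py = Cw[:, 0], Cw[:, 1]
            r2 = px**2 + py**2
            r = np.sqrt(r2)
            cos_tau = (a1**2 + r2 - lw**2) / np.where(r > 0, 2.0 * a1 * r, np.inf)
            reach_pl = (np.abs(cos_tau) <= 1.0) & reach_t3
            tau = np.arccos(np.clip(cos_tau, -1.0, 1.0))
            ang_p = np.arctan2(py, px)
            for i1, t1 in enumerate((ang_p - tau, ang_p + tau)):
                vx = px - a1 * np.cos(t1)
                vy = py - a1 * np.sin(t1)
                phi = np.arctan2(vy, vx) - np.arctan2(wy, wx)
                t2 = phi - t1
                # orientation left for the wrist: R_456 in ZYZ form
                R123 = _proximal_rotation(t1, t2, t3)
                M = np.einsum("nji,njk->nik", R123, R0)
                eul = Rotation.from_matrix(
                    np.where(np.isfinite(M), M, np.eye(3))
                ).as_euler("ZYZ")
                eul = np.atleast_2d(eul)
                for i5, (t4, t5, t6) in enumerate(
                    (
                        (eul[:, 0], -eul[:, 1], eul[:, 2]),
                        (eul[:, 0] + math.pi, eul[:, 1], eul[:, 2] + math.pi),
                    )
                ):
                    k = i3 * 4 + i1 * 2 + i5
                    t = np.column_stack([t1, t2, t3, t4, t5, t6])
                    q = _wrap_pi(t - chain.theta0)
                    # shift by 2*pi toward the limit interval when needed
                    lo, hi = chain.joint_limits[:, 0], chain.joint_limits[:, 1]
                    q = np.where(q < lo - 1e-12, q + 2 * math.pi * (q + 2 * math.pi <= hi + 1e-12), q)
                    q = np.where(q > hi + 1e-12, q - 2 * math.pi * (q - 2 * math.pi >= lo - 1e-12), q)
                    q_cand[:, k, :] = q
                    valid[:, k] = reach_pl & np.all(np.isfinite(q), axis=1)
    return q_cand, valid


def _proximal_rotation(t1, t2, t3):
    """Rotation of DH frame 3 relative to frame 0 for the wrist pattern."""
    n = len(np.atleast_1d(t1))
    phi = t1 + t2
    c, s = np.cos(phi), np.sin(phi)
    c3, s3 = np.cos(t3), np.sin(t3)
    # Rz(phi) @ Rx(90) @ Rz(t3) @ Rx(-90)
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = c * c3
    R[:, 0, 1] = -s
    R[:, 0, 2] = -c * s3
    R[:, 1, 0] = s * c3
    R[:, 1, 1] = c
    R[:, 1, 2] = -s * s3
    R[:, 2, 0] = s3
    R[:, 2, 1] = 0.0
    R[:, 2, 2] = c3
    return R


def _select_branch(chain, q_cand, valid, q_ref):
    """Pick, per sample, the valid in-limit branch closest to ``q_ref``."""
    lo, hi = chain.joint_limits[:, 0], chain.joint_limits[:, 1]
    in_lim = np.all((q_cand >= lo - 1e-9) & (q_cand <= hi + 1e-9), axis=2)
    ok = valid & in_lim
    dist = np.linalg.norm(q_cand - np.asarray(q_ref).reshape(-1, 1, 6), axis=2)
    dist = np.where(ok, dist, np.inf)
    best = np.argmin(dist, axis=1)
    q = q_cand[np.arange(len(best)), best]
    found = ok[np.arange(len(best)), best]
    return q, found


def inverse_kinematics(
    chain: DHChain,
    target: Pose,
    q_init: np.ndarray | None = None,
    *,
    pos_tol: float = 1e-7,
    rot_tol: float = 1e-9,
    max_iter: int = 200,
) -> IKResult:
    """Solve for joint angles reproducing ``target``.

    Chains with the decoupled-wrist layout are solved in closed form
    (branch nearest ``q_init``); other chains fall back to damped
    least squares.  Non-convergence is not an exception: the result
    carries the best joint vector found together with its residuals and a
    ``converged`` flag (position <= 0.5 mm and orientation <= 0.05 deg).
    """
    if q_init is None:
        q_init = chain.neutral_q
    q_init = np.asarray(q_init, dtype=float).reshape(6)
    if not np.all(np.isfinite(q_init)):
        raise InvalidInputError("q_init must be finite")
    tgt = target.matrix[None, :, :]
    if _has_decoupled_wrist(chain):
        q_cand, valid = _ik_analytic_candidates(chain, tgt)
        q, found = _select_branch(chain, q_cand, valid, q_init[None, :])
        if found[0]:
            # polish to machine precision and measure residuals
            q, conv, pos_res, rot_res = _ik_batch(
                chain, tgt, q, pos_tol=pos_tol, rot_tol=rot_tol, max_iter=20
            )
            return IKResult(
                q=q[0],
                converged=bool(conv[0]),
                position_residual_mm=float(pos_res[0]),
                orientation_residual_deg=math.degrees(float(rot_res[0])),
            )
    q, conv, pos_res, rot_res = _ik_batch(
        chain, tgt, q_init[None, :],
        pos_tol=pos_tol, rot_tol=rot_tol, max_iter=max_iter,
    )
    return IKResult(
        q=q[0],
        converged=bool(conv[0]),
        position_residual_mm=float(pos_res[0]),
        orientation_residual_deg=math.degrees(float(rot_res[0])),
    )


def ik_trajectory(
    chain: DHChain,
    targets: np.ndarray,
    q_init: np.ndarray | None = None,
    *,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint trajectories for a sequence of pose targets (N, 4, 4).

    For decoupled-wrist chains all closed-form branches are computed at
    once and branch selection walks the trajectory sequentially, keeping
    the solution continuous (the warm-start contract).  Other chains are
    solved by batched damped least squares from ``q_init``.

    Returns ``(q, converged)`` with shapes (N, 6) and (N,).
    """
    targets = np.asarray(targets, dtype=float)
    if q_init is None:
        q_init = chain.neutral_q
    q_init = np.asarray(q_init, dtype=float)
    if _has_decoupled_wrist(chain):
        q_cand, valid = _ik_analytic_candidates(chain, targets)
        lo, hi = chain.joint_limits[:, 0], chain.joint_limits[:, 1]
        ok = valid & np.all((q_cand >= lo - 1e-9) & (q_cand <= hi + 1e-9), axis=2)
        n = targets.shape[0]
        q = np.empty((n, 6))
        found = np.zeros(n, dtype=bool)
        ref = q_init if q_init.ndim == 1 else q_init[0]
        for i in range(n):
            cand_ok = np.flatnonzero(ok[i])
            if cand_ok.size:
                d = np.linalg.norm(q_cand[i, cand_ok] - ref, axis=1)
                q[i] = q_cand[i, cand_ok[np.argmin(d)]]
                found[i] = True
                ref = q[i]
            else:
                q[i] = ref
        # polish everything in one batch; unreachable samples keep the
        # last feasible configuration and are reported unconverged
        q, conv, _, _ = _ik_batch(chain, targets, q, max_iter=25)
        return q, conv
    q, conv, _, _ = _ik_batch(chain, targets, q_init, max_iter=max_iter)
    return q, conv


# ---------------------------------------------------------------------------
# anatomical head angles
# ---------------------------------------------------------------------------


def compose_head_angles(angles_deg: np.ndarray) -> np.ndarray:
    """Rotation matrices from (flexext, lateral, axial) degrees.

    Inverse of :func:`head_angles_from_matrices`; intrinsic sequence
    vertical -> anteroposterior -> mediolateral.
    """
    ang = np.asarray(angles_deg, dtype=float)
    single = ang.ndim == 1
    ang = np.atleast_2d(ang)
    # reorder to euler (Z, X, Y) = (axial, lateral, flexext) with signs
    euler = np.column_stack(
        [
            _EULER_SIGNS[0] * ang[:, 2],
            _EULER_SIGNS[1] * ang[:, 1],
            _EULER_SIGNS[2] * ang[:, 0],
        ]
    )
    R = Rotation.from_euler(_EULER_SEQ, euler, degrees=True).as_matrix()
    return R[0] if single else R


def head_angles_from_matrices(
    R: np.ndarray, R_neutral: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Angles (deg) and gimbal flags for a batch of rotation matrices.

    Decomposes ``R_neutral.T @ R`` by the fixed intrinsic sequence.  The
    flag marks samples whose middle (lateral) angle is within 0.5 deg of
    +/-90 where the decomposition is degenerate.
    """
    R = np.asarray(R, dtype=float)
    single = R.ndim == 2
    R = R.reshape(-1, 3, 3)
    rel = np.asarray(R_neutral).T @ R
    euler = Rotation.from_matrix(rel).as_euler(_EULER_SEQ, degrees=True)
    euler = np.atleast_2d(euler)
    ang = np.column_stack(
        [
            _EULER_SIGNS[2] * euler[:, 2],  # flexion_extension
            _EULER_SIGNS[1] * euler[:, 1],  # lateral_bending
            _EULER_SIGNS[0] * euler[:, 0],  # axial_rotation
        ]
    )
    degenerate = np.abs(np.abs(euler[:, 1]) - 90.0) < _GIMBAL_GUARD_DEG
    if single:
        return ang[0], degenerate[0]
    return ang, degenerate


def head_angles_from_pose(pose: Pose, neutral: Pose) -> HeadAngles:
    """Anatomical head angles of ``pose`` relative to the neutral pose."""
    ang, degen = head_angles_from_matrices(pose.rotation, neutral.rotation)
    return HeadAngles(
        flexion_extension=float(ang[0]),
        lateral_bending=float(ang[1]),
        axial_rotation=float(ang[2]),
        degenerate=bool(degen),
    )


# ---------------------------------------------------------------------------
# shipped default chain
# ---------------------------------------------------------------------------


def default_chain() -> DHChain:
    """Default brace chain satisfying all structural axis constraints.

    Link values are desk-scale millimetres produced by the design-search
    workflow on the default synthetic workspace; the base pose aligns the
    J1 axis with the mediolateral (flexion-extension) anatomical axis and
    the tool pose makes the neutral end-effector orientation the identity
    in the anatomical frame (x anterior, y left, z up).
    """
    # base: z axis of DH frame 0 along anatomical +y (subject's left)
    R_base = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]])
    base = Pose(np.zeros(3), R_base)
    a = [45.0, 95.0, 0.0, 0.0, 0.0, 0.0]
    alpha = [0.0, math.pi / 2, -math.pi / 2, math.pi / 2, -math.pi / 2, 0.0]
    d = [0.0, 0.0, 95.0, 55.0, 0.0, 130.0]
    theta0 = [
        math.radians(-115.0),
        math.radians(115.0),
        math.radians(90.0),
        math.radians(90.0),
        math.radians(90.0),
        0.0,
    ]
    limits = np.array([[-2.6, 2.6]] * 6)
    chain = DHChain(a, alpha, d, theta0, limits, base=base)
    # tool rotation chosen so the neutral end-effector frame is identity
    T_n = forward_kinematics_batch(chain, np.zeros((1, 6)))[0]
    chain.tool = Pose(np.zeros(3), T_n[:3, :3].T)
    chain.validate_structure()
    return chain
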