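"""Potentiometer-to-angle calibration and validation against motion capture.

Joint angles obtained by inverse kinematics from motion-capture head
poses are regressed on the simultaneously recorded potentiometer
voltages (per-joint polynomials, optionally refined jointly by
minimizing the reconstructed-head-angle error).  The fitted model maps a
voltage log to anatomical head angles via forward kinematics, and a
validation report compares those against the mocap reference on the
primary angle of each single-plane trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .chain import (
    DHChain,
    Pose,
    forward_kinematics_batch,
    head_angles_from_matrices,
    ik_trajectory,
)
from .design import MarkerTrial, build_reference_frame, head_frames, trunk_frames
from .errors import DegenerateFitError, InvalidInputError, SchemaError

__all__ = [
    "PRIMARY_INDEX",
    "VoltageLog",
    "AngleSeries",
    "CalibrationModel",
    "TrialErrors",
    "ValidationReport",
    "fit_calibration",
    "calibrate_session",
    "apply_calibration",
    "validation_errors",
    "joint_angles_from_markers",
    "read_voltage_csv",
    "write_voltage_csv",
]

#: column index of the primary angle for each single-plane motion
PRIMARY_INDEX = {
    "flexion_extension": 0,
    "lateral_bending": 1,
    "axial_rotation": 2,
}


@dataclass
class VoltageLog:
    """Six-channel potentiometer log (V) with a shared trigger line."""

    sample_rate: float
    time_s: np.ndarray
    volts: np.ndarray  # (N, 6), channel i <-> joint J_{i+1}
    trigger: np.ndarray
    v_supply: float = 3.3

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float).reshape(-1)
        self.volts = np.asarray(self.volts, dtype=float)
        if self.volts.shape != (self.time_s.size, 6):
            raise SchemaError(
                f"voltage array shape {self.volts.shape} does not match "
                f"{self.time_s.size} samples x 6 joints"
            )
        if not np.all(np.isfinite(self.volts)):
            raise SchemaError("voltage log has non-finite samples")
        if np.any(self.volts < -1e-9) or np.any(self.volts > self.v_supply + 1e-9):
            raise SchemaError("voltages outside [0, V_supply]")
        self.trigger = np.asarray(self.trigger, dtype=float).reshape(-1)
        if self.trigger.size != self.time_s.size:
            raise SchemaError("trigger length mismatch")

    @property
    def n_samples(self) -> int:
        return self.time_s.size


@dataclass
class AngleSeries:
    """Head-angle time series (deg) with per-sample quality flags."""

    sample_rate: float
    time_s: np.ndarray
    angles_deg: np.ndarray  # (N, 3): flexext, lateral, axial
    out_of_range: np.ndarray | None = None
    degenerate: np.ndarray | None = None


@dataclass
class CalibrationModel:
    """Per-joint polynomial voltage -> joint angle (rad) maps.

    Coefficients are in ascending power order (numpy polynomial
    convention).  ``neutral_voltages`` pin the zero of the head angles;
    ``voltage_range`` is the observed per-joint span used by the
    extrapolation guard.
    """

    degree: int
    coeffs: np.ndarray  # (6, degree + 1)
    neutral_voltages: np.ndarray  # (6,)
    voltage_range: np.ndarray  # (6, 2)
    rms_residual_rad: np.ndarray  # (6,)
    monotone: np.ndarray  # (6,) bool
    refined: bool = False
    extrapolation_guard: float = 0.05

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise InvalidInputError("polynomial degree must be >= 1")
        self.coeffs = np.asarray(self.coeffs, dtype=float).reshape(6, self.degree + 1)

    def joint_angles(self, volts: np.ndarray) -> np.ndarray:
        """Evaluate the per-joint polynomials; volts (N, 6) -> rad (N, 6)."""
        volts = np.asarray(volts, dtype=float)
        q = np.empty_like(volts)
        for j in range(6):
            q[:, j] = np.polynomial.polynomial.polyval(
                volts[:, j], self.coeffs[j]
            )
        return q

    def out_of_range_mask(self, volts: np.ndarray) -> np.ndarray:
        lo = self.voltage_range[:, 0]
        hi = self.voltage_range[:, 1]
        guard = self.extrapolation_guard * (hi - lo)
        return np.any(
            (volts < lo - guard) | (volts > hi + guard), axis=1
        )

    def to_json(self, path: str | Path) -> None:
        data = {
            "degree": self.degree,
            "coeffs": self.coeffs.tolist(),
            "neutral_voltages": self.neutral_voltages.tolist(),
            "voltage_range": self.voltage_range.tolist(),
            "rms_residual_rad": self.rms_residual_rad.tolist(),
            "monotone": [bool(m) for m in self.monotone],
            "refined": self.refined,
            "extrapolation_guard": self.extrapolation_guard,
        }
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        data = json.loads(Path(path).read_text())
        return cls(
            degree=data["degree"],
            coeffs=np.array(data["coeffs"]),
            neutral_voltages=np.array(data["neutral_voltages"]),
            voltage_range=np.array(data["voltage_range"]),
            rms_residual_rad=np.array(data["rms_residual_rad"]),
            monotone=np.array(data["monotone"], dtype=bool),
            refined=data.get("refined", False),
            extrapolation_guard=data.get("extrapolation_guard", 0.05),
        )


@dataclass
class TrialErrors:
    trial: str
    motion_type: str
    max_abs_error_deg: float
    rms_error_deg: float


@dataclass
class ValidationReport:
    trials: list[TrialErrors]
    mean_rms_deg: float
    max_abs_deg: float
    per_plane: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trial": t.trial,
                    "motion_type": t.motion_type,
                    "max_abs_error_deg": t.max_abs_error_deg,
                    "rms_error_deg": t.rms_error_deg,
                }
                for t in self.trials
            ]
        )


# ---------------------------------------------------------------------------
# mocap-side joint angles
# ---------------------------------------------------------------------------


def joint_angles_from_markers(
    trial: MarkerTrial,
    static_trial: MarkerTrial,
    chain: DHChain,
) -> tuple[np.ndarray, np.ndarray]:
    """IK joint angles and reference head angles from a dynamic trial.

    The head rigid motion relative to the static (neutral) posture is
    measured from the three head markers, expressed in the trunk frame,
    applied to the chain's neutral end-effector pose and solved by IK.

    Returns ``(q (N, 6) rad, head_angles (N, 3) deg)``.
    """
    trunk0, _ = build_reference_frame(static_trial)
    head0_p, head0_R = head_frames(static_trial)
    head0 = Pose(head0_p.mean(axis=0), _project_rotation(head0_R.mean(axis=0)))

    p, R = head_frames(trial)
    # rigid motion of the head relative to neutral, in the trunk frame
    Rt = trunk0.rotation
    dR = np.einsum(
        "ij,njk,kl->nil", Rt.T, R @ head0.rotation.T, Rt
    )
    dp = (p - head0.position) @ Rt + (
        head0.position - trunk0.position
    ) @ Rt  # head origin in trunk frame
    # pivot the neutral EE pose by the measured rigid motion
    T0 = forward_kinematics_batch(chain, chain.neutral_q[None])[0]
    p0, R0 = T0[:3, 3], T0[:3, :3]
    head0_local = (head0.position - trunk0.position) @ Rt
    targets = np.broadcast_to(np.eye(4), (len(p), 4, 4)).copy()
    targets[:, :3, :3] = dR @ R0
    targets[:, :3, 3] = dp + np.einsum("nij,j->ni", dR, p0 - head0_local)
    q, _ = ik_trajectory(chain, targets)
    angles, _ = head_angles_from_matrices(targets[:, :3, :3], R0)
    return q, angles


def _project_rotation(M: np.ndarray) -> np.ndarray:
    """Nearest rotation matrix (polar decomposition via SVD)."""
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_calibration(
    volts: np.ndarray,
    q_ik: np.ndarray,
    degree: int = 3,
    *,
    refine: bool = True,
    chain: DHChain | None = None,
    reference_angles_deg: np.ndarray | None = None,
    neutral_voltages: np.ndarray | None = None,
    max_refine_samples: int = 400,
) -> CalibrationModel:
    """Fit per-joint voltage -> angle polynomials on time-aligned samples.

    Stage 1 fits each joint independently by least squares.  Stage 2
    (``refine``, on by default; requires ``chain`` and
    ``reference_angles_deg``) jointly adjusts all coefficients to
    minimize the summed error between forward-kinematics-reconstructed
    and mocap head angles.
    """
    volts = np.asarray(volts, dtype=float)
    q_ik = np.asarray(q_ik, dtype=float)
    if volts.ndim != 2 or volts.shape[1] != 6 or volts.shape != q_ik.shape:
        raise InvalidInputError("volts and q_ik must both be (N, 6)")
    n = volts.shape[0]
    if n <= degree + 1:
        raise InvalidInputError(
            f"need more than degree + 1 = {degree + 1} samples, got {n}"
        )
    coeffs = np.empty((6, degree + 1))
    rms = np.empty(6)
    for j in range(6):
        v = volts[:, j]
        if np.ptp(v) < 1e-9:
            raise DegenerateFitError(
                f"joint J{j + 1}: constant voltage, calibration is rank deficient"
            )
        c = np.polynomial.polynomial.polyfit(v, q_ik[:, j], degree)
        coeffs[j] = c
        rms[j] = float(
            np.sqrt(np.mean((np.polynomial.polynomial.polyval(v, c) - q_ik[:, j]) ** 2))
        )
    vrange = np.column_stack([volts.min(axis=0), volts.max(axis=0)])
    if neutral_voltages is None:
        neutral_voltages = volts[0].copy()
    refined = False
    if refine:
        if chain is None or reference_angles_deg is None:
            raise InvalidInputError(
                "refine=True requires chain and reference_angles_deg"
            )
        coeffs = _refine_coeffs(
            coeffs, volts, q_ik,
            np.asarray(reference_angles_deg, dtype=float),
            chain, max_refine_samples,
        )
        refined = True
        for j in range(6):
            rms[j] = float(
                np.sqrt(
                    np.mean(
                        (
                            np.polynomial.polynomial.polyval(volts[:, j], coeffs[j])
                            - q_ik[:, j]
                        )
                        ** 2
                    )
                )
            )
    monotone = _monotone_flags(coeffs, vrange)
    return CalibrationModel(
        degree=degree,
        coeffs=coeffs,
        neutral_voltages=np.asarray(neutral_voltages, dtype=float),
        voltage_range=vrange,
        rms_residual_rad=rms,
        monotone=monotone,
        refined=refined,
    )


def _monotone_flags(coeffs: np.ndarray, vrange: np.ndarray) -> np.ndarray:
    flags = np.empty(6, dtype=bool)
    for j in range(6):
        v = np.linspace(vrange[j, 0], vrange[j, 1], 101)
        dq = np.diff(np.polynomial.polynomial.polyval(v, coeffs[j]))
        flags[j] = bool(np.all(dq > 0) or np.all(dq < 0))
    return flags


def _refine_coeffs(coeffs, volts, q_ik, ref_angles_deg, chain, max_samples):
    n = volts.shape[0]
    idx = np.linspace(0, n - 1, min(n, max_samples)).astype(int)
    v = volts[idx]
    qi = q_ik[idx]
    ref = ref_angles_deg[idx]
    T0 = forward_kinematics_batch(chain, chain.neutral_q[None])[0]
    R0 = T0[:3, :3]
    shape = coeffs.shape
    # light per-joint anchor: keeps the head-angle objective from pushing
    # coefficients along its null space (J1/J2 share an axis direction)
    w_joint = 0.2

    def resid(x):
        c = x.reshape(shape)
        q = np.empty_like(v)
        for j in range(6):
            q[:, j] = np.polynomial.polynomial.polyval(v[:, j], c[j])
        T = forward_kinematics_batch(chain, q)
        ang, _ = head_angles_from_matrices(T[:, :3, :3], R0)
        return np.concatenate(
            [(ang - ref).ravel(), w_joint * np.degrees(q - qi).ravel()]
        )

    out = least_squares(
        resid, coeffs.ravel(), method="lm", max_nfev=60 * coeffs.size
    )
    return out.x.reshape(shape)


def calibrate_session(
    markers,
    voltages_by_motion: dict[str, VoltageLog],
    chain: DHChain,
    *,
    degree: int = 3,
    refine: bool = True,
) -> CalibrationModel:
    """Fit a calibration model from one session's markers and voltages.

    Pools all dynamic trials: mocap head poses -> IK joint angles,
    linearly interpolated onto each voltage log's timeline (shared
    clock), then per-joint polynomial fit with optional pose-error
    refinement.  Neutral voltages are taken from the static posture
    (median of the lead-in samples of each log).
    """
    static = markers.static_trial()
    V, Q, REF, NEU = [], [], [], []
    for motion, vlog in voltages_by_motion.items():
        if motion not in markers.trials:
            raise SchemaError(f"no marker trial for motion {motion!r}")
        trial = markers.trials[motion]
        q_ik, ref_ang = joint_angles_from_markers(trial, static, chain)
        qi = np.column_stack(
            [np.interp(vlog.time_s, trial.time_s, q_ik[:, j]) for j in range(6)]
        )
        ri = np.column_stack(
            [np.interp(vlog.time_s, trial.time_s, ref_ang[:, j]) for j in range(3)]
        )
        V.append(vlog.volts)
        Q.append(qi)
        REF.append(ri)
        # lead-in samples (first half second) approximate the neutral posture
        k = max(1, int(0.5 * vlog.sample_rate))
        NEU.append(np.median(vlog.volts[:k], axis=0))
    return fit_calibration(
        np.vstack(V),
        np.vstack(Q),
        degree=degree,
        refine=refine,
        chain=chain,
        reference_angles_deg=np.vstack(REF),
        neutral_voltages=np.mean(NEU, axis=0),
    )


# ---------------------------------------------------------------------------
# application and validation
# ---------------------------------------------------------------------------


def apply_calibration(
    model: CalibrationModel, voltages: VoltageLog, chain: DHChain
) -> AngleSeries:
    """Voltage log -> joint angles -> FK -> anatomical head angles (deg).

    Samples outside the calibrated voltage range (plus the extrapolation
    guard) are flagged, not dropped; gimbal-degenerate samples are
    flagged likewise.
    """
    if model.coeffs.shape[0] != 6:
        raise InvalidInputError("model/chain joint count mismatch")
    q = model.joint_angles(voltages.volts)
    oor = model.out_of_range_mask(voltages.volts)
    q_neutral = model.joint_angles(model.neutral_voltages[None, :])[0]
    T = forward_kinematics_batch(chain, q)
    T_neutral = forward_kinematics_batch(chain, q_neutral[None])[0]
    angles, degen = head_angles_from_matrices(T[:, :3, :3], T_neutral[:3, :3])
    return AngleSeries(
        sample_rate=voltages.sample_rate,
        time_s=voltages.time_s,
        angles_deg=angles,
        out_of_range=oor,
        degenerate=degen,
    )


def primary_angle_errors(
    brace: np.ndarray, reference: np.ndarray
) -> tuple[float, float]:
    """Max-abs and RMS difference between two primary-angle series (deg)."""
    brace = np.asarray(brace, dtype=float).reshape(-1)
    reference = np.asarray(reference, dtype=float).reshape(-1)
    if brace.size != reference.size:
        raise InvalidInputError("series length mismatch after resampling")
    diff = brace - reference
    return float(np.max(np.abs(diff))), float(np.sqrt(np.mean(diff**2)))


def validation_errors(
    trials: list[tuple[str, str, np.ndarray, np.ndarray]]
) -> ValidationReport:
    """Validation report over (trial_id, motion_type, brace, mocap) tuples.

    ``brace`` and ``mocap`` are (N, 3) head-angle arrays on a common
    timeline; errors are computed on the primary angle of each trial's
    motion plane.  Aggregates: mean RMS over trials (pooled and per
    plane) and the maximum absolute error over the whole group.
    """
    if not trials:
        raise InvalidInputError("validation needs at least one trial")
    rows = []
    for trial_id, motion, brace, mocap in trials:
        if motion not in PRIMARY_INDEX:
            raise InvalidInputError(f"unknown motion type {motion!r}")
        k = PRIMARY_INDEX[motion]
        brace = np.asarray(brace, dtype=float)
        mocap = np.asarray(mocap, dtype=float)
        b = brace[:, k] if brace.ndim == 2 else brace
        m = mocap[:, k] if mocap.ndim == 2 else mocap
        max_abs, rms = primary_angle_errors(b, m)
        rows.append(TrialErrors(trial_id, motion, max_abs, rms))
    per_plane: dict[str, dict[str, float]] = {}
    for motion in PRIMARY_INDEX:
        sel = [t for t in rows if t.motion_type == motion]
        if sel:
            per_plane[motion] = {
                "mean_rms_deg": float(np.mean([t.rms_error_deg for t in sel])),
                "max_abs_deg": float(np.max([t.max_abs_error_deg for t in sel])),
            }
    return ValidationReport(
        trials=rows,
        mean_rms_deg=float(np.mean([t.rms_error_deg for t in rows])),
        max_abs_deg=float(np.max([t.max_abs_error_deg for t in rows])),
        per_plane=per_plane,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_voltage_csv(log: VoltageLog, path: str | Path) -> None:
    data = {"time_s": log.time_s}
    for j in range(6):
        data[f"v{j + 1}"] = log.volts[:, j]
    data["trigger"] = log.trigger
    pd.DataFrame(data).to_csv(path, index=False)


def read_voltage_csv(
    path: str | Path, sample_rate: float = 100.0, v_supply: float = 3.3
) -> VoltageLog:
    df = pd.read_csv(path)
    cols = ["time_s"] + [f"v{j}" for j in range(1, 7)] + ["trigger"]
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing column {c!r}")
    volts = df[[f"v{j}" for j in range(1, 7)]].to_numpy(dtype=float)
    return VoltageLog(
        sample_rate=sample_rate,
        time_s=df["time_s"].to_numpy(dtype=float),
        volts=volts,
        trigger=df["trigger"].to_numpy(dtype=float),
        v_supply=v_supply,
    )
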