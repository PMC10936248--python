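"""Synthetic digital twin of a clinic session.

Generates ground-truthed marker trajectories (200 Hz), potentiometer
voltages (100 Hz) and surface EMG (1.5 kHz) for the single-plane motion
protocol: biphasic raised-cosine head-angle cycles (neutral -> one
extreme -> opposite extreme -> neutral), joint trajectories via inverse
kinematics, a monotone nonlinear voltage-angle sensor map, and EMG
bursts phase-locked to the movement according to the rope activation
model (e.g. right axial rotation driven by left SCM, right SC and left
TR).  A shared trigger edge is embedded in the voltage and EMG streams.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .calibration import VoltageLog
from .chain import (
    DHChain,
    compose_head_angles,
    default_chain,
    forward_kinematics_batch,
    ik_trajectory,
)
from .design import MARKER_LABELS, MarkerSession, MarkerTrial
from .errors import GenerationError, InvalidInputError
from .signals import EMG_CHANNELS, EMGRecording

__all__ = [
    "BurstParams",
    "RopeActivation",
    "SensorMap",
    "SyntheticSpec",
    "SyntheticSession",
    "default_sensor_map",
    "rope_activation_schedule",
    "angle_profile",
    "generate_session",
    "apply_visit_deltas",
]

#: directions per motion type; the first entry is the positive angle sign
MOTION_DIRECTIONS = {
    "axial_rotation": ("right", "left"),
    "lateral_bending": ("right", "left"),
    "flexion_extension": ("extension", "flexion"),
}

#: static marker layout (mm, anatomical frame at C7).  Trunk markers are
#: placed so the constructed trunk frame is exactly the anatomical frame.
MARKER_STATIC = {
    "C7": np.array([0.0, 0.0, 0.0]),
    "CHEST": np.array([140.0, 0.0, 0.0]),
    "ACR_L": np.array([0.0, 180.0, -10.0]),
    "ACR_R": np.array([0.0, -180.0, -10.0]),
    "C1": np.array([30.0, 0.0, 110.0]),
    "HEAD_TOP": np.array([21.0, 0.0, 265.8]),
    "HEAD_L": np.array([0.0, 85.0, 190.0]),
    "HEAD_R": np.array([0.0, -85.0, 190.0]),
}

HEAD_RIGID = ("C1", "HEAD_TOP", "HEAD_L", "HEAD_R")


# ---------------------------------------------------------------------------
# sensor map
# ---------------------------------------------------------------------------


@dataclass
class SensorMap:
    """Monotone per-joint cubic map between voltage and joint angle.

    ``theta = k1 * (v - v0) + k3 * (v - v0)**3`` (rad); the inverse is
    evaluated by Newton iterations (the map is strictly increasing).
    """

    k1: np.ndarray
    k3: np.ndarray
    v0: np.ndarray
    v_supply: float = 3.3

    def __post_init__(self) -> None:
        self.k1 = np.asarray(self.k1, dtype=float).reshape(6)
        self.k3 = np.asarray(self.k3, dtype=float).reshape(6)
        self.v0 = np.asarray(self.v0, dtype=float).reshape(6)
        if np.any(self.k1 <= 0) or np.any(self.k3 < 0):
            raise InvalidInputError("sensor map must be strictly increasing")

    def joint_angles(self, volts: np.ndarray) -> np.ndarray:
        u = np.asarray(volts, dtype=float) - self.v0
        return self.k1 * u + self.k3 * u**3

    def voltage_from_angle(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        u = q / self.k1
        for _ in range(40):
            f = self.k1 * u + self.k3 * u**3 - q
            fp = self.k1 + 3.0 * self.k3 * u**2
            step = f / fp
            u = u - step
            if np.max(np.abs(step)) < 1e-14:
                break
        return u + self.v0


def default_sensor_map() -> SensorMap:
    """Distinct mild cubic nonlinearity per joint, 3.3 V full scale."""
    return SensorMap(
        k1=[1.00, 1.10, 0.95, 1.20, 1.05, 0.90],
        k3=[0.20, 0.15, 0.25, 0.10, 0.30, 0.22],
        v0=[1.65, 1.60, 1.70, 1.65, 1.55, 1.75],
    )


# ---------------------------------------------------------------------------
# rope activation schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BurstParams:
    center_pct: float
    width_pct: float
    amplitude: float


@dataclass(frozen=True)
class RopeActivation:
    motion_type: str
    direction: str
    muscles: tuple[str, ...]
    #: relative burst amplitude per muscle (1.0 = prime mover)
    amplitudes: dict[str, float]


def _mirror(muscle: str) -> str:
    if muscle.endswith("_L"):
        return muscle[:-2] + "_R"
    return muscle[:-2] + "_L"


def rope_activation_schedule(motion_type: str, direction: str) -> RopeActivation:
    """Active muscle set for one motion direction (rope model).

    Right axial rotation: left SCM + right SC + left TR; left lateral
    bending: the three left-side muscles; flexion: both SCM (with
    low-level TR co-activation); extension: both SC.  Left/right swaps
    mirror exactly.
    """
    if motion_type not in MOTION_DIRECTIONS:
        raise InvalidInputError(f"unknown motion type {motion_type!r}")
    if direction not in MOTION_DIRECTIONS[motion_type]:
        raise InvalidInputError(
            f"unknown direction {direction!r} for {motion_type}"
        )
    if motion_type == "axial_rotation":
        base = {"SCM_L": 1.0, "SC_R": 1.0, "TR_L": 1.0}  # right rotation
        amps = base if direction == "right" else {
            _mirror(m): a for m, a in base.items()
        }
    elif motion_type == "lateral_bending":
        base = {"SCM_L": 1.0, "SC_L": 1.0, "TR_L": 1.0}  # left bending
        amps = base if direction == "left" else {
            _mirror(m): a for m, a in base.items()
        }
    else:  # flexion_extension
        if direction == "flexion":
            amps = {"SCM_L": 1.0, "SCM_R": 1.0, "TR_L": 0.3, "TR_R": 0.3}
        else:
            amps = {"SC_L": 1.0, "SC_R": 1.0}
    return RopeActivation(
        motion_type=motion_type,
        direction=direction,
        muscles=tuple(sorted(amps)),
        amplitudes=amps,
    )


# ---------------------------------------------------------------------------
# spec
# ---------------------------------------------------------------------------


def _default_amplitudes() -> dict:
    return {
        "axial_rotation": {"right": 60.0, "left": 60.0},
        "lateral_bending": {"right": 40.0, "left": 40.0},
        "flexion_extension": {"extension": 45.0, "flexion": 50.0},
    }


@dataclass
class SyntheticSpec:
    """Everything that parameterises one synthetic session."""

    motion_types: tuple[str, ...] = tuple(MOTION_DIRECTIONS)
    cycles_per_trial: int = 5
    cycle_period_s: float = 3.6
    amplitude_deg: dict = field(default_factory=_default_amplitudes)
    coupling_fraction: float = 0.1
    marker_noise_mm: float = 1.0
    voltage_noise_fraction_fs: float = 0.005
    marker_rate_hz: float = 200.0
    brace_rate_hz: float = 100.0
    emg_rate_hz: float = 1500.0
    lead_in_s: float = 1.0
    lead_out_s: float = 1.0
    trigger_time_s: float = 0.5
    #: EMG burst phase parameters: prime movers toward the first extreme
    #: burst early in the cycle, toward the second extreme mid-cycle
    burst_center_first_pct: float = 15.0
    burst_center_second_pct: float = 50.0
    burst_width_pct: float = 5.0
    burst_amplitude_mv: float = 0.5
    emg_baseline_mv: float = 0.02
    cardiac_rate_hz: float = 1.2
    cardiac_amplitude_mv: float = 0.04
    #: centre of head rotation relative to the wrist point C (mm)
    rotation_center_offset_mm: tuple[float, float, float] = (0.0, 0.0, -40.0)
    #: per-muscle burst timing shift (% cycle), applied on top
    timing_shift_pct: dict = field(default_factory=dict)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles_per_trial < 1:
            raise InvalidInputError("cycles_per_trial must be >= 1")
        for motion, dirs in self.amplitude_deg.items():
            for dname, amp in dirs.items():
                if amp < 0:
                    raise InvalidInputError(
                        f"amplitude for {motion}/{dname} must be >= 0"
                    )


def apply_visit_deltas(
    spec: SyntheticSpec,
    amplitude_deltas: dict | None = None,
    timing_shifts: dict | None = None,
) -> SyntheticSpec:
    """Spec for a follow-up visit: amplitude changes (deg) per
    motion/direction and per-muscle EMG timing shifts (% cycle)."""
    out = replace(spec)
    out.amplitude_deg = copy.deepcopy(spec.amplitude_deg)
    out.timing_shift_pct = dict(spec.timing_shift_pct)
    for motion, dirs in (amplitude_deltas or {}).items():
        for dname, delta in dirs.items():
            out.amplitude_deg[motion][dname] = max(
                0.0, out.amplitude_deg[motion][dname] + delta
            )
    for muscle, shift in (timing_shifts or {}).items():
        out.timing_shift_pct[muscle] = (
            out.timing_shift_pct.get(muscle, 0.0) + shift
        )
    return out


# ---------------------------------------------------------------------------
# angle profile
# ---------------------------------------------------------------------------


def _raised_cosine(v0: float, v1: float, frac: np.ndarray) -> np.ndarray:
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * frac))


def angle_profile(
    t: np.ndarray,
    amplitude1: float,
    amplitude2: float,
    period_s: float,
    n_cycles: int,
    lead_in_s: float,
) -> tuple[np.ndarray, dict]:
    """Biphasic raised-cosine primary-angle profile with ground truth.

    Each cycle: neutral -> +amplitude1 (at 25%) -> -amplitude2 (at 75%)
    -> neutral, C1-smooth.  Returns the angle series and a ground-truth
    dict with cycle boundary and extremum times.
    """
    x = np.zeros_like(t)
    boundaries = [lead_in_s + k * period_s for k in range(n_cycles + 1)]
    ext1_times = []
    ext2_times = []
    for k in range(n_cycles):
        t0 = lead_in_s + k * period_s
        seg1 = (t >= t0) & (t < t0 + 0.25 * period_s)
        seg2 = (t >= t0 + 0.25 * period_s) & (t < t0 + 0.75 * period_s)
        seg3 = (t >= t0 + 0.75 * period_s) & (t < t0 + period_s)
        x[seg1] = _raised_cosine(
            0.0, amplitude1, (t[seg1] - t0) / (0.25 * period_s)
        )
        x[seg2] = _raised_cosine(
            amplitude1, -amplitude2,
            (t[seg2] - t0 - 0.25 * period_s) / (0.5 * period_s),
        )
        x[seg3] = _raised_cosine(
            -amplitude2, 0.0,
            (t[seg3] - t0 - 0.75 * period_s) / (0.25 * period_s),
        )
        ext1_times.append(t0 + 0.25 * period_s)
        ext2_times.append(t0 + 0.75 * period_s)
    truth = {
        "boundaries_s": boundaries,
        "extremum1_s": ext1_times,
        "extremum2_s": ext2_times,
    }
    return x, truth


def _head_angle_series(spec: SyntheticSpec, motion: str, t: np.ndarray):
    """(N, 3) head-angle array (deg) plus ground truth for one trial."""
    d1, d2 = MOTION_DIRECTIONS[motion]
    a1 = spec.amplitude_deg[motion][d1]
    a2 = spec.amplitude_deg[motion][d2]
    primary, truth = angle_profile(
        t, a1, a2, spec.cycle_period_s, spec.cycles_per_trial, spec.lead_in_s
    )
    # sign convention: the first-listed direction is the positive one
    k = {"flexion_extension": 0, "lateral_bending": 1, "axial_rotation": 2}[
        motion
    ]
    angles = np.zeros((t.size, 3))
    angles[:, k] = primary
    for other in range(3):
        if other != k:
            angles[:, other] = spec.coupling_fraction * primary
    truth["primary_index"] = k
    truth["amplitudes_deg"] = (a1, a2)
    return angles, truth


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSession:
    spec: SyntheticSpec
    chain: DHChain
    sensor_map: SensorMap
    markers: MarkerSession
    voltages: dict[str, VoltageLog]
    emg: dict[str, EMGRecording]
    ground_truth: dict
    participant: str = "sim"
    visit: str = "pre"


def _pose_targets(chain: DHChain, angles_deg: np.ndarray, center: np.ndarray):
    """Rigid head poses: rotation about ``center`` applied to neutral P."""
    T0 = forward_kinematics_batch(chain, chain.neutral_q[None])[0]
    R = compose_head_angles(angles_deg)
    n = angles_deg.shape[0]
    tg = np.broadcast_to(np.eye(4), (n, 4, 4)).copy()
    tg[:, :3, :3] = R @ T0[:3, :3]
    tg[:, :3, 3] = center + np.einsum(
        "nij,j->ni", R, T0[:3, 3] - center
    )
    return tg


def _check_reachable(chain, spec, center):
    for motion in spec.motion_types:
        d1, d2 = MOTION_DIRECTIONS[motion]
        for dname, sign in ((d1, 1.0), (d2, -1.0)):
            amp = spec.amplitude_deg[motion][dname]
            ang = np.zeros((1, 3))
            k = {"flexion_extension": 0, "lateral_bending": 1,
                 "axial_rotation": 2}[motion]
            ang[0, k] = sign * amp
            tg = _pose_targets(chain, ang, center)
            _, conv = ik_trajectory(chain, tg)
            if not conv[0]:
                raise GenerationError(
                    f"prescribed amplitude {amp} deg unreachable in plane "
                    f"{motion} ({dname})"
                )


def _emg_trial(
    spec: SyntheticSpec,
    motion: str,
    duration_s: float,
    rng: np.random.Generator,
) -> tuple[EMGRecording, dict]:
    fs = spec.emg_rate_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    d1, d2 = MOTION_DIRECTIONS[motion]
    act1 = rope_activation_schedule(motion, d1)
    act2 = rope_activation_schedule(motion, d2)

    burst_centers: dict[str, list[float]] = {ch: [] for ch in EMG_CHANNELS}
    burst_amp: dict[str, float] = {ch: 0.0 for ch in EMG_CHANNELS}
    center_pct: dict[str, float] = {}
    for act, base_pct in (
        (act1, spec.burst_center_first_pct),
        (act2, spec.burst_center_second_pct),
    ):
        for muscle, rel in act.amplitudes.items():
            pct = base_pct + spec.timing_shift_pct.get(muscle, 0.0)
            center_pct[muscle] = pct
            burst_amp[muscle] = max(burst_amp[muscle], rel)
            for k in range(spec.cycles_per_trial):
                burst_centers[muscle].append(
                    spec.lead_in_s
                    + (k + pct / 100.0) * spec.cycle_period_s
                )

    sigma_s = spec.burst_width_pct / 100.0 * spec.cycle_period_s
    sos = sps.butter(4, (60.0, 200.0), btype="bandpass", fs=fs, output="sos")
    channels = {}
    for ch in EMG_CHANNELS:
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
        # flatten the carrier's own short-time envelope so the linear
        # envelope of the product tracks the burst modulation faithfully
        own_env = (
            pd.Series(np.abs(carrier))
            .rolling(75, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
        carrier = carrier / np.maximum(own_env, 1e-12)
        rms = np.sqrt(np.mean(carrier**2))
        if rms > 0:
            carrier /= rms
        mod = np.zeros(n)
        for c in burst_centers[ch]:
            mod += np.exp(-0.5 * ((t - c) / sigma_s) ** 2)
        mod *= burst_amp[ch] * spec.burst_amplitude_mv
        x = carrier * mod
        x += spec.emg_baseline_mv * rng.standard_normal(n)
        x += _cardiac_train(t, spec, rng)
        channels[ch] = x
    trigger = (t >= spec.trigger_time_s).astype(float)
    rec = EMGRecording(
        sample_rate=fs, time_s=t, channels=channels, trigger=trigger,
    )
    truth = {
        "burst_centers_s": {
            ch: list(v) for ch, v in burst_centers.items() if v
        },
        "burst_center_pct": center_pct,
        "active_muscles": sorted(
            set(act1.muscles) | set(act2.muscles)
        ),
    }
    return rec, truth


def _cardiac_train(t, spec, rng):
    """Biphasic spike train at the cardiac rate (phase jittered)."""
    if spec.cardiac_amplitude_mv <= 0:
        return np.zeros_like(t)
    out = np.zeros_like(t)
    period = 1.0 / spec.cardiac_rate_hz
    phase = rng.uniform(0, period)
    width = 0.02
    beat = phase
    while beat < t[-1]:
        u = (t - beat) / width
        out += -u * np.exp(-0.5 * u**2) * spec.cardiac_amplitude_mv * np.e**0.5
        beat += period
    return out


def generate_session(
    spec: SyntheticSpec,
    chain: DHChain | None = None,
    sensor_map: SensorMap | None = None,
    *,
    participant: str = "sim",
    visit: str = "pre",
    streams: tuple[str, ...] = ("markers", "voltages", "emg"),
) -> SyntheticSession:
    """Generate one complete ground-truthed session.

    ``streams`` selects which acquisition streams to synthesise (the
    cohort recovery workflow only needs voltages, which avoids the cost
    of marker and EMG synthesis).  With ``spec.random_seed`` fixed the
    output is bitwise reproducible.
    """
    if chain is None:
        chain = default_chain()
    if sensor_map is None:
        sensor_map = default_sensor_map()
    rng = np.random.default_rng(spec.random_seed)
    C0 = chain.concurrency_point(chain.neutral_q)
    center = C0 + np.asarray(spec.rotation_center_offset_mm, dtype=float)
    _check_reachable(chain, spec, center)

    duration = (
        spec.lead_in_s
        + spec.cycles_per_trial * spec.cycle_period_s
        + spec.lead_out_s
    )
    trials: dict[str, MarkerTrial] = {}
    voltages: dict[str, VoltageLog] = {}
    emg: dict[str, EMGRecording] = {}
    truth: dict = {"trials": {}, "center_mm": center.tolist()}

    if "markers" in streams:
        n_static = int(round(2.0 * spec.marker_rate_hz))
        t_static = np.arange(n_static) / spec.marker_rate_hz
        markers = {
            label: MARKER_STATIC[label]
            + spec.marker_noise_mm
            * rng.standard_normal((n_static, 3))
            for label in MARKER_LABELS
        }
        trials["static"] = MarkerTrial(
            kind="static", time_s=t_static, markers=markers
        )

    for motion in spec.motion_types:
        trial_truth: dict = {}
        # brace-rate ground truth and joint trajectory
        n100 = int(round(duration * spec.brace_rate_hz))
        t100 = np.arange(n100) / spec.brace_rate_hz
        angles100, prof_truth = _head_angle_series(spec, motion, t100)
        tg100 = _pose_targets(chain, angles100, center)
        q100, conv = ik_trajectory(chain, tg100)
        if not np.all(conv):
            raise GenerationError(
                f"IK failed on {int(np.sum(~conv))} samples of {motion}"
            )
        trial_truth.update(prof_truth)
        trial_truth["time_s"] = t100
        trial_truth["angles_deg"] = angles100
        trial_truth["q_rad"] = q100
        trial_truth["boundary_samples"] = [
            int(round(b * spec.brace_rate_hz))
            for b in prof_truth["boundaries_s"]
        ]

        if "voltages" in streams:
            v = sensor_map.voltage_from_angle(q100)
            v = v + (
                spec.voltage_noise_fraction_fs
                * sensor_map.v_supply
                * rng.standard_normal(v.shape)
            )
            if np.any(v < 0) or np.any(v > sensor_map.v_supply):
                raise GenerationError(
                    f"sensor voltages exceed supply range in {motion}"
                )
            trig = (t100 >= spec.trigger_time_s).astype(float)
            voltages[motion] = VoltageLog(
                sample_rate=spec.brace_rate_hz,
                time_s=t100,
                volts=v,
                trigger=trig,
                v_supply=sensor_map.v_supply,
            )

        if "markers" in streams:
            n200 = int(round(duration * spec.marker_rate_hz))
            t200 = np.arange(n200) / spec.marker_rate_hz
            angles200, _ = _head_angle_series(spec, motion, t200)
            R200 = compose_head_angles(angles200)
            markers = {}
            for label in MARKER_LABELS:
                x0 = MARKER_STATIC[label]
                if label in HEAD_RIGID:
                    pos = center + np.einsum(
                        "nij,j->ni", R200, x0 - center
                    )
                else:
                    pos = np.broadcast_to(x0, (n200, 3)).copy()
                pos = pos + spec.marker_noise_mm * rng.standard_normal(
                    (n200, 3)
                )
                markers[label] = pos
            trials[motion] = MarkerTrial(
                kind="dynamic", time_s=t200, markers=markers
            )
            trial_truth["marker_time_s"] = t200
            trial_truth["angles200_deg"] = angles200

        if "emg" in streams:
            emg_rec, emg_truth = _emg_trial(spec, motion, duration, rng)
            emg_rec.participant = participant
            emg_rec.visit = visit
            emg[motion] = emg_rec
            trial_truth.update(emg_truth)

        truth["trials"][motion] = trial_truth

    session = SyntheticSession(
        spec=spec,
        chain=chain,
        sensor_map=sensor_map,
        markers=MarkerSession(
            sample_rate=spec.marker_rate_hz, trials=trials
        ),
        voltages=voltages,
        emg=emg,
        ground_truth=truth,
        participant=participant,
        visit=visit,
    )
    return session
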