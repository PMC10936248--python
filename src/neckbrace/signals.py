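"""Angle filtering, EMG envelope pipeline and trigger synchronization.

The EMG pipeline follows the fixed order: optional cardiac-artifact
suppression, DC-offset removal, 60-200 Hz band-pass, full-wave
rectification, 300-sample (0.2 s) centered moving average, and
normalization of each channel by its largest envelope value across all
recordings of the participant's visit.  All filters are zero-phase
(forward-backward) so envelope and angle peak timing is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InvalidInputError, SchemaError, SynchronizationError

__all__ = [
    "EMG_CHANNELS",
    "EMGRecording",
    "EnvelopeSeries",
    "SyncedRecording",
    "filter_angles",
    "process_emg",
    "synchronize",
    "first_trigger_time",
    "read_emg_csv",
    "write_emg_csv",
]

EMG_CHANNELS = ("SCM_L", "SCM_R", "SC_L", "SC_R", "TR_L", "TR_R")

#: reflective padding, 3x the filter order
_PAD_FACTOR = 3


@dataclass
class EMGRecording:
    """Raw six-channel surface EMG with a shared digital trigger line."""

    sample_rate: float
    time_s: np.ndarray
    channels: dict[str, np.ndarray]
    trigger: np.ndarray
    participant: str = ""
    visit: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float).reshape(-1)
        n = self.time_s.size
        for label in EMG_CHANNELS:
            if label not in self.channels:
                raise SchemaError(f"EMG recording missing channel {label!r}")
            arr = np.asarray(self.channels[label], dtype=float).reshape(-1)
            if arr.size != n:
                raise SchemaError(f"EMG channel {label!r} length mismatch")
            if not np.all(np.isfinite(arr)):
                raise SchemaError(f"EMG channel {label!r} has non-finite samples")
            self.channels[label] = arr
        self.trigger = np.asarray(self.trigger, dtype=float).reshape(-1)
        if self.trigger.size != n:
            raise SchemaError("trigger length mismatch")

    @property
    def n_samples(self) -> int:
        return self.time_s.size


@dataclass
class EnvelopeSeries:
    """Normalized linear envelopes, one per EMG channel, values in [0, 1]."""

    sample_rate: float
    time_s: np.ndarray
    channels: dict[str, np.ndarray]
    normalization: dict[str, float] = field(default_factory=dict)


@dataclass
class SyncedRecording:
    """Brace and EMG streams on a common clock (t = 0 at the trigger).

    ``brace_time``/``emg_time`` are the shifted, overlap-cropped time
    axes; index arrays select the retained samples of the originals.
    """

    brace: object
    emg: object
    brace_time: np.ndarray
    emg_time: np.ndarray
    brace_index: np.ndarray
    emg_index: np.ndarray
    offset_s: float

    def envelope_on_brace_timeline(self, env: EnvelopeSeries) -> dict[str, np.ndarray]:
        """Linearly interpolate envelopes onto the brace timeline."""
        t_env = self.emg_time
        out = {}
        for label, ch in env.channels.items():
            out[label] = np.interp(self.brace_time, t_env, ch[self.emg_index])
        return out


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _zero_phase_filter(sos, x: np.ndarray, order: int) -> np.ndarray:
    """Forward-backward sosfiltfilt with reflective padding, 3x the
    effective filter order (band-pass doubles the design order)."""
    padlen = _PAD_FACTOR * order
    if x.shape[0] <= padlen:
        raise InvalidInputError(
            f"series too short ({x.shape[0]} samples) for zero-phase filtering"
        )
    return sps.sosfiltfilt(sos, x, axis=0, padtype="even", padlen=padlen)


def filter_angles(
    angles: np.ndarray,
    sample_rate: float,
    cutoff_hz: float = 6.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filtering of head-angle streams.

    Accepts (N,) or (N, k) arrays; default 4th order at 6 Hz.
    """
    angles = np.asarray(angles, dtype=float)
    if not np.all(np.isfinite(angles)):
        raise InvalidInputError("angle series has non-finite samples")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=sample_rate, output="sos")
    return _zero_phase_filter(sos, angles, order)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrink-at-edges behaviour."""
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def _suppress_cardiac(
    x: np.ndarray, sample_rate: float, rate_hz_band=(0.7, 2.5)
) -> np.ndarray:
    """Template-subtraction suppression of cardiac spikes.

    Detects periodic artifact peaks on a low-passed copy, ensemble
    averages a window around them and subtracts the template at every
    detected beat.  Off by default in the pipeline; the 60-200 Hz
    band-pass already removes most ECG energy.
    """
    lp = sps.sosfiltfilt(
        sps.butter(2, 30.0, btype="low", fs=sample_rate, output="sos"), x
    )
    min_dist = int(sample_rate / rate_hz_band[1])
    height = 3.0 * np.std(lp)
    peaks, _ = sps.find_peaks(np.abs(lp), height=height, distance=min_dist)
    if peaks.size < 3:
        return x
    half = int(0.05 * sample_rate)
    segs = [
        x[p - half : p + half]
        for p in peaks
        if p - half >= 0 and p + half <= x.size
    ]
    if len(segs) < 3:
        return x
    template = np.mean(segs, axis=0)
    out = x.copy()
    for p in peaks:
        if p - half >= 0 and p + half <= x.size:
            out[p - half : p + half] -= template
    return out


def envelope_stages(
    raw: EMGRecording,
    *,
    band_hz: tuple[float, float] = (60.0, 200.0),
    order: int = 4,
    window_samples: int = 300,
    cardiac_suppression: bool = False,
) -> dict[str, np.ndarray]:
    """Steps (a)-(e): pre-normalization envelope per channel."""
    if raw.sample_rate <= 2 * band_hz[1]:
        raise InvalidInputError(
            "sample rate must exceed twice the band-pass upper edge"
        )
    sos = sps.butter(
        order, band_hz, btype="bandpass", fs=raw.sample_rate, output="sos"
    )
    out = {}
    for label in EMG_CHANNELS:
        x = raw.channels[label]
        if cardiac_suppression:
            x = _suppress_cardiac(x, raw.sample_rate)
        x = x - np.mean(x)
        x = _zero_phase_filter(sos, x, 2 * order)
        x = np.abs(x)
        out[label] = _moving_average(x, window_samples)
    return out


def process_emg(
    raw: EMGRecording,
    visit_pool: list[EMGRecording],
    *,
    band_hz: tuple[float, float] = (60.0, 200.0),
    order: int = 4,
    window_samples: int = 300,
    cardiac_suppression: bool = False,
) -> EnvelopeSeries:
    """Full envelope pipeline including visit-wide normalization (step f).

    ``visit_pool`` must contain ``raw`` and only recordings of the same
    participant and visit; each channel is divided by its maximum
    envelope value over the pool (all-zero channels stay zero).
    """
    if not visit_pool:
        raise InvalidInputError("visit pool must be non-empty")
    if not any(r is raw for r in visit_pool):
        raise InvalidInputError("visit pool must include the processed recording")
    for rec in visit_pool:
        if rec.participant != raw.participant or rec.visit != raw.visit:
            raise InvalidInputError(
                "visit pool mixes participants or visits"
            )
    kwargs = dict(
        band_hz=band_hz,
        order=order,
        window_samples=window_samples,
        cardiac_suppression=cardiac_suppression,
    )
    own = envelope_stages(raw, **kwargs)
    maxima = {label: np.max(env) for label, env in own.items()}
    for rec in visit_pool:
        envs = own if rec is raw else envelope_stages(rec, **kwargs)
        for label in EMG_CHANNELS:
            maxima[label] = max(maxima[label], float(np.max(envs[label])))
    channels = {}
    for label in EMG_CHANNELS:
        m = maxima[label]
        channels[label] = own[label] / m if m > 0 else np.zeros_like(own[label])
    return EnvelopeSeries(
        sample_rate=raw.sample_rate,
        time_s=raw.time_s,
        channels=channels,
        normalization=maxima,
    )


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------


def first_trigger_time(time_s: np.ndarray, trigger: np.ndarray) -> float:
    """Time of the first rising edge of a 0/1 trigger line."""
    trig = np.asarray(trigger, dtype=float) > 0.5
    if trig.size == 0 or not trig.any():
        raise SynchronizationError("no trigger edge found in stream")
    if trig[0]:
        # already high at the start: treat sample 0 as the edge
        return float(time_s[0])
    edges = np.flatnonzero(~trig[:-1] & trig[1:])
    if edges.size == 0:
        raise SynchronizationError("no rising trigger edge found in stream")
    return float(time_s[edges[0] + 1])


def synchronize(brace, emg) -> SyncedRecording:
    """Align a brace stream and an EMG stream on their trigger edges.

    Both objects must expose ``time_s`` and ``trigger`` arrays.  The
    first rising edge of each stream defines its t = 0; streams are then
    cropped to the overlapping interval.
    """
    tb = first_trigger_time(brace.time_s, brace.trigger)
    te = first_trigger_time(emg.time_s, emg.trigger)
    brace_t = np.asarray(brace.time_s, dtype=float) - tb
    emg_t = np.asarray(emg.time_s, dtype=float) - te
    t_end = min(brace_t[-1], emg_t[-1])
    bi = np.flatnonzero((brace_t >= 0) & (brace_t <= t_end + 1e-12))
    ei = np.flatnonzero((emg_t >= 0) & (emg_t <= t_end + 1e-12))
    if bi.size == 0 or ei.size == 0:
        raise SynchronizationError("streams do not overlap after alignment")
    return SyncedRecording(
        brace=brace,
        emg=emg,
        brace_time=brace_t[bi],
        emg_time=emg_t[ei],
        brace_index=bi,
        emg_index=ei,
        offset_s=float(te - tb),
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_emg_csv(rec: EMGRecording, path: str | Path) -> None:
    data = {"time_s": rec.time_s}
    for label in EMG_CHANNELS:
        data[label.lower()] = rec.channels[label]
    data["trigger"] = rec.trigger
    pd.DataFrame(data).to_csv(path, index=False)


def read_emg_csv(
    path: str | Path,
    sample_rate: float = 1500.0,
    participant: str = "",
    visit: str = "",
) -> EMGRecording:
    df = pd.read_csv(path)
    for col in ("time_s", "trigger"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    channels = {}
    for label in EMG_CHANNELS:
        col = label.lower()
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
        channels[label] = df[col].to_numpy(dtype=float)
    return EMGRecording(
        sample_rate=sample_rate,
        time_s=df["time_s"].to_numpy(dtype=float),
        channels=channels,
        trigger=df["trigger"].to_numpy(dtype=float),
        participant=participant,
        visit=visit,
    )
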