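"""Session manifests and on-disk layout.

A session is a JSON manifest referencing per-trial CSV files (markers,
voltages, EMG) for one participant and visit, plus an optional YAML
config.  ``load_session`` parses and validates everything up front so
downstream code can assume clean streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import VoltageLog, read_voltage_csv, write_voltage_csv
from .config import Config, load_config
from .design import MarkerSession, MarkerTrial, read_marker_csv, write_marker_csv
from .errors import SchemaError
from .signals import EMGRecording, read_emg_csv, write_emg_csv

__all__ = ["SessionManifest", "Session", "load_session", "write_session"]

VISITS = ("pre", "post")


@dataclass
class TrialEntry:
    motion_type: str
    markers: str | None = None
    voltages: str | None = None
    emg: str | None = None


@dataclass
class SessionManifest:
    participant: str
    visit: str
    trials: list[TrialEntry]
    static_markers: str | None = None
    config: str | None = None

    def __post_init__(self) -> None:
        if self.visit not in VISITS:
            raise SchemaError(f"visit must be one of {VISITS}, got {self.visit!r}")


@dataclass
class Session:
    manifest: SessionManifest
    config: Config
    markers: MarkerSession | None
    voltages: dict[str, VoltageLog] = field(default_factory=dict)
    emg: dict[str, EMGRecording] = field(default_factory=dict)


def _check_rate(time_s: np.ndarray, expected_hz: float, path: str) -> None:
    if time_s.size < 2:
        return
    dt = np.median(np.diff(time_s))
    if dt <= 0:
        raise SchemaError(f"{path}: non-increasing timestamps")
    actual = 1.0 / dt
    if abs(actual - expected_hz) > 0.01 * expected_hz:
        raise SchemaError(
            f"{path}: sample spacing {dt:.6g} s implies {actual:.6g} Hz, "
            f"configured rate is {expected_hz:g} Hz"
        )


def load_session(manifest_path: str | Path) -> Session:
    """Load and validate all streams referenced by a session manifest."""
    manifest_path = Path(manifest_path)
    try:
        raw = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{manifest_path}: invalid JSON ({exc})") from exc
    for key in ("participant", "visit", "trials"):
        if key not in raw:
            raise SchemaError(f"{manifest_path}: missing manifest key {key!r}")
    manifest = SessionManifest(
        participant=raw["participant"],
        visit=raw["visit"],
        trials=[TrialEntry(**t) for t in raw["trials"]],
        static_markers=raw.get("static_markers"),
        config=raw.get("config"),
    )
    root = manifest_path.parent
    config = load_config(root / manifest.config if manifest.config else None)

    trials: dict[str, MarkerTrial] = {}
    if manifest.static_markers:
        path = root / manifest.static_markers
        trials["static"] = read_marker_csv(path, kind="static")
        _check_rate(trials["static"].time_s, config.rates.marker_hz, str(path))

    voltages: dict[str, VoltageLog] = {}
    emg: dict[str, EMGRecording] = {}
    for entry in manifest.trials:
        if entry.markers:
            path = root / entry.markers
            trial = read_marker_csv(path, kind="dynamic")
            _check_rate(trial.time_s, config.rates.marker_hz, str(path))
            trials[entry.motion_type] = trial
        if entry.voltages:
            path = root / entry.voltages
            log = read_voltage_csv(path, sample_rate=config.rates.brace_hz)
            _check_rate(log.time_s, config.rates.brace_hz, str(path))
            voltages[entry.motion_type] = log
        if entry.emg:
            path = root / entry.emg
            rec = read_emg_csv(
                path,
                sample_rate=config.rates.emg_hz,
                participant=manifest.participant,
                visit=manifest.visit,
            )
            _check_rate(rec.time_s, config.rates.emg_hz, str(path))
            emg[entry.motion_type] = rec

    markers = (
        MarkerSession(sample_rate=config.rates.marker_hz, trials=trials)
        if trials
        else None
    )
    return Session(
        manifest=manifest,
        config=config,
        markers=markers,
        voltages=voltages,
        emg=emg,
    )


def write_session(session, out_dir: str | Path) -> Path:
    """Write a synthetic session to CSV files plus a manifest.

    Returns the manifest path.  Ground truth is stored alongside as
    JSON for downstream verification.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    static_name = None
    if session.markers is not None and "static" in session.markers.trials:
        static_name = "markers_static.csv"
        write_marker_csv(session.markers.trials["static"], out_dir / static_name)
    motions = set(session.voltages) | set(session.emg)
    if session.markers is not None:
        motions |= {
            k for k, t in session.markers.trials.items() if t.kind == "dynamic"
        }
    for motion in sorted(motions):
        entry = {"motion_type": motion}
        if session.markers is not None and motion in session.markers.trials:
            name = f"markers_{motion}.csv"
            write_marker_csv(session.markers.trials[motion], out_dir / name)
            entry["markers"] = name
        if motion in session.voltages:
            name = f"voltages_{motion}.csv"
            write_voltage_csv(session.voltages[motion], out_dir / name)
            entry["voltages"] = name
        if motion in session.emg:
            name = f"emg_{motion}.csv"
            write_emg_csv(session.emg[motion], out_dir / name)
            entry["emg"] = name
        entries.append(entry)
    manifest = {
        "participant": session.participant,
        "visit": session.visit,
        "trials": entries,
        "static_markers": static_name,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    truth = getattr(session, "ground_truth", None)
    if truth is not None:
        (out_dir / "ground_truth.json").write_text(
            json.dumps(_jsonable(truth), indent=2)
        )
    return manifest_path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
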