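"""Central configuration with protocol defaults.

Every acquisition/processing constant lives here: sample rates (200 /
100 / 1500 Hz), the 6 Hz angle low-pass, the 60-200 Hz EMG band-pass,
the 300-sample (0.2 s) envelope window, segmentation hysteresis and the
significance level.  ``validate`` enforces internal consistency,
including the identity window_samples / emg_rate == window duration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["Config", "load_config"]


@dataclass
class RatesConfig:
    marker_hz: float = 200.0
    brace_hz: float = 100.0
    emg_hz: float = 1500.0


@dataclass
class FiltersConfig:
    angle_lowpass_hz: float = 6.0
    angle_filter_order: int = 4
    emg_band_hz: tuple[float, float] = (60.0, 200.0)
    emg_filter_order: int = 4
    envelope_window_samples: int = 300
    envelope_window_s: float = 0.2
    cardiac_suppression: bool = False


@dataclass
class CalibrationConfig:
    degree: int = 3
    refine: bool = True
    extrapolation_guard: float = 0.05


@dataclass
class SegmentationConfig:
    enter_fraction: float = 0.10
    exit_fraction: float = 0.20


@dataclass
class StatsConfig:
    alpha: float = 0.05


@dataclass
class DesignConfig:
    grid_step_mm: float = 5.0
    grid_span_mm: float = 30.0
    n_eval: int = 200
    tol_reach_mm: float = 2.0
    limit_margin_deg: float = 5.0


@dataclass
class Config:
    rates: RatesConfig = field(default_factory=RatesConfig)
    filters: FiltersConfig = field(default_factory=FiltersConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    design: DesignConfig = field(default_factory=DesignConfig)

    def validate(self) -> "Config":
        f, r = self.filters, self.rates
        if r.marker_hz <= 0 or r.brace_hz <= 0 or r.emg_hz <= 0:
            raise ConfigError("sample rates must be positive")
        if f.angle_lowpass_hz >= r.brace_hz / 2:
            raise ConfigError("angle low-pass cutoff must be below Nyquist")
        lo, hi = f.emg_band_hz
        if not 0 < lo < hi:
            raise ConfigError("EMG band edges must satisfy 0 < low < high")
        if r.emg_hz <= 2 * hi:
            raise ConfigError(
                "EMG sample rate must exceed twice the band-pass upper edge"
            )
        if f.envelope_window_samples < 1:
            raise ConfigError("envelope window must be >= 1 sample")
        implied = f.envelope_window_samples / r.emg_hz
        if abs(implied - f.envelope_window_s) > 1e-12:
            raise ConfigError(
                f"envelope window inconsistent: {f.envelope_window_samples} "
                f"samples at {r.emg_hz} Hz is {implied} s, config says "
                f"{f.envelope_window_s} s"
            )
        if self.calibration.degree < 1 or self.calibration.degree > 5:
            raise ConfigError("calibration degree must be in 1..5")
        s = self.segmentation
        if not 0 < s.enter_fraction < s.exit_fraction < 1:
            raise ConfigError(
                "segmentation fractions must satisfy 0 < enter < exit < 1"
            )
        if not 0 < self.stats.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        return self

    @property
    def envelope_window_s(self) -> float:
        """Envelope window duration implied by samples and EMG rate."""
        return self.filters.envelope_window_samples / self.rates.emg_hz

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        def build(klass, key):
            section = data.get(key, {}) or {}
            known = {f.name for f in klass.__dataclass_fields__.values()}
            unknown = set(section) - known
            if unknown:
                raise ConfigError(
                    f"unknown keys in config section {key!r}: {sorted(unknown)}"
                )
            if "emg_band_hz" in section:
                section["emg_band_hz"] = tuple(section["emg_band_hz"])
            return klass(**section)

        cfg = cls(
            rates=build(RatesConfig, "rates"),
            filters=build(FiltersConfig, "filters"),
            calibration=build(CalibrationConfig, "calibration"),
            segmentation=build(SegmentationConfig, "segmentation"),
            stats=build(StatsConfig, "stats"),
            design=build(DesignConfig, "design"),
        )
        return cfg.validate()


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a YAML config; defaults when no path is given."""
    if path is None:
        return Config().validate()
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return Config().validate()
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return Config.from_dict(data)
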