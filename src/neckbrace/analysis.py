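"""Movement-cycle segmentation, time normalization and outcome statistics.

A single-plane trial is a continuous stream of biphasic cycles
(neutral -> one extreme -> opposite extreme -> neutral).  Cycles are
delimited by returns of the primary angle into a neutral band with
hysteresis, resampled onto a 101-point percent-cycle grid, averaged, and
summarised as completion time, peak angles, range of motion and EMG peak
timing.  Pre/post comparisons use paired t statistics with 95% CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .errors import InvalidInputError, SegmentationError

__all__ = [
    "MOTION_TYPES",
    "CycleSpan",
    "MovementCycle",
    "CycleOutcome",
    "PairedStats",
    "segment_cycles",
    "extract_cycles",
    "time_normalize_and_average",
    "compute_outcomes",
    "paired_stats",
]

MOTION_TYPES = ("axial_rotation", "lateral_bending", "flexion_extension")

#: percent-cycle grid (0..100 inclusive)
PCT_GRID = np.linspace(0.0, 100.0, 101)


@dataclass
class CycleSpan:
    """Index span of one detected cycle within a trial."""

    start: int
    end: int  # inclusive
    extremum1: int
    extremum2: int


@dataclass
class MovementCycle:
    """One movement cycle resampled to 101 points (0-100% cycle)."""

    motion_type: str
    angle: np.ndarray  # (101,) deg, primary angle
    envelopes: dict[str, np.ndarray] = field(default_factory=dict)
    duration_s: float = 0.0
    subblocks_pct: tuple[float, float] = (25.0, 75.0)

    def __post_init__(self) -> None:
        if self.motion_type not in MOTION_TYPES:
            raise InvalidInputError(f"unknown motion type {self.motion_type!r}")
        self.angle = np.asarray(self.angle, dtype=float).reshape(-1)
        if self.angle.size != 101:
            raise InvalidInputError("cycle angle must have 101 samples")
        if self.duration_s <= 0:
            raise InvalidInputError("cycle duration must be positive")
        b1, b2 = self.subblocks_pct
        if not 0.0 < b1 < b2 < 100.0:
            raise InvalidInputError("sub-block boundaries must be increasing in (0, 100)")


@dataclass
class CycleOutcome:
    completion_time_s: float
    max_angle_deg: float
    min_angle_deg: float
    rom_deg: float
    emg_peak_timing_pct: dict[str, float] = field(default_factory=dict)


@dataclass
class PairedStats:
    n: int
    mean_diff: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: int
    p_value: float
    significant: bool
    degenerate: bool = False


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_cycles(
    angle: np.ndarray,
    *,
    enter_fraction: float = 0.10,
    exit_fraction: float = 0.20,
) -> list[CycleSpan]:
    """Delimit biphasic movement cycles of a primary-angle series.

    The neutral band is ``enter_fraction`` of the trial's peak |angle|;
    an excursion starts when |angle| exceeds ``exit_fraction`` of the
    peak (hysteresis).  A cycle is complete when the series re-enters the
    neutral band after excursions to both sides; its boundaries are
    refined to the local minimum of |angle| within each neutral dwell.
    Partial excursions at the end of the trial are discarded.
    """
    x = np.asarray(angle, dtype=float).reshape(-1)
    if x.size < 3 or not np.all(np.isfinite(x)):
        raise InvalidInputError("angle series must be finite with >= 3 samples")
    peak = float(np.max(np.abs(x)))
    if peak <= 0.0:
        return []
    enter_thr = enter_fraction * peak
    exit_thr = exit_fraction * peak
    if abs(x[0]) > enter_thr:
        raise SegmentationError(
            "trial does not start inside the neutral band"
        )
    in_band = np.abs(x) <= enter_thr
    outside = np.abs(x) >= exit_thr

    spans: list[CycleSpan] = []
    n = x.size
    # initial boundary: latest sample of the leading neutral dwell whose
    # |angle| attains the dwell minimum (exact zero for noiseless input)
    first_out = np.argmax(outside) if outside.any() else n
    if first_out == 0 or first_out >= n:
        return []
    lead = np.abs(x[:first_out])
    start = int(first_out - 1 - np.argmin(lead[::-1]))

    i = int(first_out)
    while True:
        # one excursion to each side, tracking both extrema
        sides_seen: list[int] = []
        ext_idx: dict[int, int] = {}
        cycle_done = False
        while i < n:
            if in_band[i] and len(sides_seen) >= 2:
                cycle_done = True
                break
            if not in_band[i]:
                s = 1 if x[i] > 0 else -1
                if np.abs(x[i]) >= exit_thr:
                    if not sides_seen or sides_seen[-1] != s:
                        sides_seen.append(s)
                    if s not in ext_idx or np.abs(x[i]) > np.abs(x[ext_idx[s]]):
                        ext_idx[s] = i
                elif s in ext_idx and np.abs(x[i]) > np.abs(x[ext_idx[s]]):
                    ext_idx[s] = i
            i += 1
        if not cycle_done:
            break  # trailing partial excursion: discard
        # refine the end boundary to the dwell minimum of |angle|
        dwell_end = i
        while dwell_end < n and in_band[dwell_end]:
            dwell_end += 1
        dwell = np.abs(x[i:dwell_end])
        end = int(i + np.argmin(dwell))
        e1, e2 = ext_idx[sides_seen[0]], ext_idx[sides_seen[1]]
        if start < e1 < e2 < end:
            spans.append(CycleSpan(start=start, end=end, extremum1=e1, extremum2=e2))
        start = end
        # advance to the next excursion
        while i < n and not outside[i]:
            i += 1
        if i >= n:
            break
    if not spans:
        warnings.warn("no complete movement cycles detected", stacklevel=2)
    return spans


def extract_cycles(
    angle: np.ndarray,
    sample_rate: float,
    motion_type: str,
    envelopes: dict[str, np.ndarray] | None = None,
    *,
    enter_fraction: float = 0.10,
    exit_fraction: float = 0.20,
) -> list[MovementCycle]:
    """Segment a trial and resample each cycle to the percent-cycle grid."""
    spans = segment_cycles(
        angle, enter_fraction=enter_fraction, exit_fraction=exit_fraction
    )
    angle = np.asarray(angle, dtype=float).reshape(-1)
    cycles = []
    for sp in spans:
        sl = slice(sp.start, sp.end + 1)
        t = np.arange(sp.start, sp.end + 1, dtype=float)
        grid = sp.start + (sp.end - sp.start) * PCT_GRID / 100.0
        resampled = np.interp(grid, t, angle[sl])
        env = {}
        if envelopes:
            for label, ch in envelopes.items():
                ch = np.asarray(ch, dtype=float).reshape(-1)
                env[label] = np.interp(grid, t, ch[sl])
        span = sp.end - sp.start
        cycles.append(
            MovementCycle(
                motion_type=motion_type,
                angle=resampled,
                envelopes=env,
                duration_s=span / sample_rate,
                subblocks_pct=(
                    100.0 * (sp.extremum1 - sp.start) / span,
                    100.0 * (sp.extremum2 - sp.start) / span,
                ),
            )
        )
    return cycles


# ---------------------------------------------------------------------------
# normalization / averaging
# ---------------------------------------------------------------------------


def time_normalize_and_average(cycles: list[MovementCycle]) -> MovementCycle:
    """Pointwise mean cycle on the 101-point grid.

    Cycles whose first extremum has the opposite sign to the first
    cycle's are time-reversed before averaging so opposite-phase cycles
    do not cancel.
    """
    if not cycles:
        raise InvalidInputError("need at least one cycle to average")
    motion = cycles[0].motion_type
    if any(c.motion_type != motion for c in cycles):
        raise InvalidInputError("cannot average cycles of mixed motion types")

    def first_ext_sign(c: MovementCycle) -> float:
        k = int(round(c.subblocks_pct[0]))
        return np.sign(c.angle[k]) or 1.0

    ref_sign = first_ext_sign(cycles[0])
    aligned_angles = []
    aligned_envs: dict[str, list[np.ndarray]] = {
        k: [] for k in cycles[0].envelopes
    }
    boundaries = []
    for c in cycles:
        if first_ext_sign(c) != ref_sign:
            aligned_angles.append(c.angle[::-1])
            for k in aligned_envs:
                aligned_envs[k].append(c.envelopes[k][::-1])
            b1, b2 = c.subblocks_pct
            boundaries.append((100.0 - b2, 100.0 - b1))
        else:
            aligned_angles.append(c.angle)
            for k in aligned_envs:
                aligned_envs[k].append(c.envelopes[k])
            boundaries.append(c.subblocks_pct)
    mean_b = tuple(np.mean(boundaries, axis=0))
    return MovementCycle(
        motion_type=motion,
        angle=np.mean(aligned_angles, axis=0),
        envelopes={k: np.mean(v, axis=0) for k, v in aligned_envs.items()},
        duration_s=float(np.mean([c.duration_s for c in cycles])),
        subblocks_pct=mean_b,
    )


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


def compute_outcomes(cycle: MovementCycle) -> CycleOutcome:
    """Peak angles, RoM, completion time and EMG peak timing of a cycle.

    Peak timing is the argmax of each envelope in percent cycle; exact
    ties resolve to the earliest sample.
    """
    max_a = float(np.max(cycle.angle))
    min_a = float(np.min(cycle.angle))
    timing = {
        label: float(PCT_GRID[int(np.argmax(env))])
        for label, env in cycle.envelopes.items()
    }
    return CycleOutcome(
        completion_time_s=cycle.duration_s,
        max_angle_deg=max_a,
        min_angle_deg=min_a,
        rom_deg=max_a - min_a,
        emg_peak_timing_pct=timing,
    )


# ---------------------------------------------------------------------------
# paired statistics
# ---------------------------------------------------------------------------


def paired_stats(
    pre: np.ndarray, post: np.ndarray, alpha: float = 0.05
) -> PairedStats:
    """Two-sided paired t test of post - pre with a 95% CI.

    Zero-variance differences degenerate: all-zero -> p = 1, flagged and
    not significant; constant non-zero -> p = 0, significant, point CI.
    """
    pre = np.asarray(pre, dtype=float).reshape(-1)
    post = np.asarray(post, dtype=float).reshape(-1)
    if pre.size != post.size:
        raise InvalidInputError("pre and post must be paired (equal length)")
    n = pre.size
    if n < 2:
        raise InvalidInputError("paired test needs n >= 2")
    d = post - pre
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedStats(
                n=n, mean_diff=0.0, ci_low=0.0, ci_high=0.0,
                t_stat=float("nan"), df=df, p_value=1.0,
                significant=False, degenerate=True,
            )
        t = float("inf") if mean > 0 else float("-inf")
        return PairedStats(
            n=n, mean_diff=mean, ci_low=mean, ci_high=mean,
            t_stat=t, df=df, p_value=0.0, significant=True, degenerate=True,
        )
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2.0 * float(spstats.t.sf(abs(t), df))
    tcrit = float(spstats.t.ppf(1.0 - alpha / 2.0, df))
    return PairedStats(
        n=n,
        mean_diff=mean,
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
        t_stat=float(t),
        df=df,
        p_value=p,
        significant=p < alpha,
    )
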