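"""Design-phase workspace analysis.

Builds trunk/head reference frames from an eight-marker motion-capture
session, re-expresses head-marker trajectories in the trunk frame (C7
origin), fits the rotation-centre sphere of the head-top cloud, searches
DH link parameters so a candidate chain reaches the whole workspace while
keeping J4 on the neck side of the shoulder plane, and derives joint
operating ranges from observed trajectories.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .chain import DHChain, Pose, point_on_chain_batch
from .errors import (
    DegenerateGeometryError,
    InvalidInputError,
    SchemaError,
)

__all__ = [
    "MARKER_LABELS",
    "MarkerTrial",
    "MarkerSession",
    "WorkspaceCloud",
    "SphereFit",
    "ClearanceSpec",
    "build_reference_frame",
    "head_frames",
    "to_trunk_frame",
    "fit_sphere",
    "farthest_point_subsample",
    "search_dh_parameters",
    "check_clearance",
    "derive_joint_limits",
    "read_marker_csv",
    "write_marker_csv",
]

MARKER_LABELS = (
    "C7",
    "CHEST",
    "ACR_L",
    "ACR_R",
    "C1",
    "HEAD_TOP",
    "HEAD_L",
    "HEAD_R",
)

#: markers forming the head rigid body (headband)
HEAD_MARKERS = ("C1", "HEAD_TOP", "HEAD_L", "HEAD_R")
#: markers forming the trunk rigid body
TRUNK_MARKERS = ("C7", "CHEST", "ACR_L", "ACR_R")


@dataclass
class MarkerTrial:
    """One labelled trial: time stamps plus per-marker (N, 3) mm arrays."""

    kind: str  # "static" or "dynamic"
    time_s: np.ndarray
    markers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float).reshape(-1)
        n = self.time_s.size
        for label in MARKER_LABELS:
            if label not in self.markers:
                raise SchemaError(f"marker trial missing label {label!r}")
        for label, arr in self.markers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 3):
                raise SchemaError(
                    f"marker {label!r} has shape {arr.shape}, expected ({n}, 3)"
                )
            if not np.all(np.isfinite(arr)):
                raise SchemaError(f"marker {label!r} has non-finite samples")
            self.markers[label] = arr
        if self.kind not in ("static", "dynamic"):
            raise SchemaError(f"unknown trial kind {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return self.time_s.size


@dataclass
class MarkerSession:
    """A set of named marker trials recorded at a common sample rate."""

    sample_rate: float = 200.0
    trials: dict[str, MarkerTrial] = field(default_factory=dict)

    def static_trial(self) -> MarkerTrial:
        for trial in self.trials.values():
            if trial.kind == "static":
                return trial
        raise SchemaError("session has no static trial")

    def dynamic_trials(self) -> dict[str, MarkerTrial]:
        return {k: t for k, t in self.trials.items() if t.kind == "dynamic"}


@dataclass
class WorkspaceCloud:
    """Point cloud (mm) expressed in the trunk frame (C7 marker origin)."""

    points: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("workspace cloud has non-finite points")
        self.points = pts


@dataclass
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float


@dataclass
class ClearanceSpec:
    """Separating plane through C1 and both acromion markers.

    ``head_point`` identifies the head side of the plane; J4 must stay on
    the opposite (C1/neck) side.
    """

    c1: np.ndarray
    acr_l: np.ndarray
    acr_r: np.ndarray
    head_point: np.ndarray


# ---------------------------------------------------------------------------
# reference frames
# ---------------------------------------------------------------------------


def _orthonormal_frame(x_raw: np.ndarray, y_raw: np.ndarray) -> np.ndarray:
    """Right-handed frame from an anterior-ish and a leftward-ish vector.

    x is primary (anterior), z = x cross y_left (up), y recomputed.
    """
    nx = np.linalg.norm(x_raw)
    ny = np.linalg.norm(y_raw)
    if nx < 1e-9 or ny < 1e-9:
        raise DegenerateGeometryError("zero-length axis vector")
    x = x_raw / nx
    z = np.cross(x, y_raw / ny)
    nz = np.linalg.norm(z)
    if nz < 1e-6:
        raise DegenerateGeometryError("frame-defining markers are collinear")
    z = z / nz
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def _trunk_frame_single(c7, chest, acr_l, acr_r) -> Pose:
    R = _orthonormal_frame(chest - c7, acr_l - acr_r)
    return Pose(c7, R)


def _head_frame_single(head_l, head_r, head_top) -> Pose:
    y_raw = head_l - head_r
    mid = 0.5 * (head_l + head_r)
    z_raw = head_top - mid
    ny = np.linalg.norm(y_raw)
    nz = np.linalg.norm(z_raw)
    if ny < 1e-9 or nz < 1e-9:
        raise DegenerateGeometryError("zero-length head axis vector")
    x = np.cross(y_raw / ny, z_raw / nz)
    nx = np.linalg.norm(x)
    if nx < 1e-6:
        raise DegenerateGeometryError("head markers are collinear")
    x = x / nx
    y = y_raw / ny
    z = np.cross(x, y)
    return Pose(head_top, np.column_stack([x, y, z]))


def build_reference_frame(trial: MarkerTrial) -> tuple[Pose, Pose]:
    """Trunk and head frames from the time-averaged static trial.

    Trunk: origin at mean C7, x toward CHEST (anterior), lateral axis from
    the acromion pair, orthogonalized right-handed.  Head: origin at mean
    HEAD_TOP, lateral axis HEAD_R -> HEAD_L, up axis toward HEAD_TOP.
    """
    if trial.n_samples < 1:
        raise InvalidInputError("static trial must contain at least 1 sample")
    mean = {k: trial.markers[k].mean(axis=0) for k in MARKER_LABELS}
    trunk = _trunk_frame_single(
        mean["C7"], mean["CHEST"], mean["ACR_L"], mean["ACR_R"]
    )
    head = _head_frame_single(mean["HEAD_L"], mean["HEAD_R"], mean["HEAD_TOP"])
    return trunk, head


def head_frames(trial: MarkerTrial) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample head frame: positions (N, 3) and rotations (N, 3, 3)."""
    hl = trial.markers["HEAD_L"]
    hr = trial.markers["HEAD_R"]
    ht = trial.markers["HEAD_TOP"]
    n = trial.n_samples
    pos = np.empty((n, 3))
    rot = np.empty((n, 3, 3))
    for i in range(n):
        pose = _head_frame_single(hl[i], hr[i], ht[i])
        pos[i] = pose.position
        rot[i] = pose.rotation
    return pos, rot


def trunk_frames(trial: MarkerTrial) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample trunk frame: positions (N, 3) and rotations (N, 3, 3)."""
    c7 = trial.markers["C7"]
    ch = trial.markers["CHEST"]
    al = trial.markers["ACR_L"]
    ar = trial.markers["ACR_R"]
    n = trial.n_samples
    pos = np.empty((n, 3))
    rot = np.empty((n, 3, 3))
    for i in range(n):
        pose = _trunk_frame_single(c7[i], ch[i], al[i], ar[i])
        pos[i] = pose.position
        rot[i] = pose.rotation
    return pos, rot


def to_trunk_frame(
    points: np.ndarray,
    trunk_positions: np.ndarray,
    trunk_rotations: np.ndarray,
    source: str = "",
) -> WorkspaceCloud:
    """Re-express per-sample points in the per-sample trunk frame.

    Removes trunk motion; a point riding on the C7 marker maps to the
    origin.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    trunk_positions = np.asarray(trunk_positions, dtype=float).reshape(-1, 3)
    trunk_rotations = np.asarray(trunk_rotations, dtype=float).reshape(-1, 3, 3)
    if not (len(points) == len(trunk_positions) == len(trunk_rotations)):
        raise InvalidInputError(
            "points and trunk poses must have matching sample counts"
        )
    rel = points - trunk_positions
    local = np.einsum("nji,nj->ni", trunk_rotations, rel)
    return WorkspaceCloud(local, source=source)


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------


def fit_sphere(cloud: WorkspaceCloud) -> SphereFit:
    """Least-squares sphere through a point cloud.

    Algebraic linear solve (Coope's method) refined by geometric
    orthogonal-distance least squares; the reported residual is the RMS
    of ``| |p - c| - r |``.
    """
    pts = cloud.points
    if pts.shape[0] < 4:
        raise InvalidInputError("sphere fit needs at least 4 points")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.sum(pts**2, axis=1)
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < 1e-8 * sv[0]:
        raise DegenerateGeometryError(
            "point cloud is coplanar or otherwise degenerate for sphere fitting"
        )
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("algebraic sphere fit produced r^2 <= 0")
    radius = float(np.sqrt(r2))

    def resid(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    out = least_squares(resid, np.append(center, radius), method="lm")
    center, radius = out.x[:3], float(out.x[3])
    rms = float(np.sqrt(np.mean(resid(out.x) ** 2)))
    return SphereFit(center=center, radius=abs(radius), rms_residual=rms)


# ---------------------------------------------------------------------------
# exhaustive DH parameter search
# ---------------------------------------------------------------------------


def farthest_point_subsample(points: np.ndarray, n: int) -> np.ndarray:
    """Greedy farthest-point subsample of a cloud (deterministic)."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) <= n:
        return points
    chosen = [int(np.argmax(np.linalg.norm(points - points.mean(0), axis=1)))]
    dist = np.linalg.norm(points - points[chosen[0]], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return points[chosen]


@dataclass
class SearchResult:
    chain: DHChain
    params: dict
    reach_fraction: float
    total_link_length: float
    clearance_ok: bool


def search_dh_parameters(
    cloud: WorkspaceCloud,
    template: DHChain,
    grid: Mapping[tuple[str, int], Iterable[float]],
    clearance: ClearanceSpec | None = None,
    *,
    n_eval: int = 200,
    tol_reach_mm: float = 2.0,
    rng: np.random.Generator | None = None,
) -> list[SearchResult]:
    """Exhaustive grid search over chain link parameters.

    ``grid`` maps ``("a"|"d", joint_index 1..6)`` to candidate values in
    mm; the Cartesian product is evaluated.  A candidate is feasible iff
    every evaluated cloud point is reachable within ``tol_reach_mm`` with
    joints inside their limits and, when a clearance plane is given, J4
    stays on the C1 side throughout.  Results are sorted by total link
    length (compactness) ascending.
    """
    keys = list(grid.keys())
    values = [list(grid[k]) for k in keys]
    if not keys or any(len(v) == 0 for v in values):
        raise InvalidInputError("parameter grid must be non-empty")
    for kind, joint in keys:
        if kind not in ("a", "d") or not 1 <= joint <= 6:
            raise InvalidInputError(f"bad grid key {(kind, joint)!r}")
    pts = farthest_point_subsample(cloud.points, n_eval)

    feasible: list[SearchResult] = []
    for combo in itertools.product(*values):
        a = template.a.copy()
        d = template.d.copy()
        params = {}
        for (kind, joint), val in zip(keys, combo):
            (a if kind == "a" else d)[joint - 1] = val
            params[f"{kind}{joint}"] = float(val)
        candidate = template.with_params(a=a, d=d)
        # per-candidate deterministic restarts: feasibility of a candidate
        # must not depend on its position in the grid (monotone property)
        cand_rng = rng or np.random.default_rng(
            abs(hash(tuple(round(v, 9) for v in combo))) % 2**32
        )
        ok, q_sol = _reach_with_solutions(
            candidate, pts, tol_reach_mm, rng=cand_rng
        )
        frac = float(np.mean(ok))
        if frac < 1.0:
            continue
        clear_ok = True
        if clearance is not None:
            clear_ok, _ = check_clearance(
                candidate, q_sol, clearance.c1, clearance.acr_l,
                clearance.acr_r, head_point=clearance.head_point,
            )
        if clear_ok:
            feasible.append(
                SearchResult(
                    chain=candidate,
                    params=params,
                    reach_fraction=frac,
                    total_link_length=candidate.total_link_length(),
                    clearance_ok=clear_ok,
                )
            )
    feasible.sort(key=lambda r: r.total_link_length)
    return feasible


def _reach_with_solutions(chain, points, tol_mm, rng):
    """Position-only reach mask plus the joint solutions used."""
    from .chain import _ik_batch  # internal reuse

    n = len(points)
    targets = np.broadcast_to(np.eye(4), (n, 4, 4)).copy()
    targets[:, :3, 3] = points
    q, _, res, _ = _ik_batch(
        chain, targets, chain.neutral_q, position_only=True,
        pos_tol=tol_mm * 1e-3, max_iter=120,
    )
    ok = res <= tol_mm
    for _ in range(8):
        if np.all(ok):
            break
        idx = np.flatnonzero(~ok)
        lo, hi = chain.joint_limits[:, 0], chain.joint_limits[:, 1]
        seeds = rng.uniform(lo, hi, size=(idx.size, 6))
        q2, _, res2, _ = _ik_batch(
            chain, targets[idx], seeds, position_only=True,
            pos_tol=tol_mm * 1e-3, max_iter=120,
        )
        good = res2 <= tol_mm
        q[idx[good]] = q2[good]
        ok[idx] |= good
    return ok, q


# ---------------------------------------------------------------------------
# clearance plane and joint ranges
# ---------------------------------------------------------------------------


def clearance_plane(c1, acr_l, acr_r) -> tuple[np.ndarray, np.ndarray]:
    """Plane through C1 and both acromions: returns (point, unit normal)."""
    c1 = np.asarray(c1, dtype=float)
    e1 = np.asarray(acr_l, dtype=float) - c1
    e2 = np.asarray(acr_r, dtype=float) - c1
    n = np.cross(e1, e2)
    nn = np.linalg.norm(n)
    if nn < 1e-9 * max(np.linalg.norm(e1), np.linalg.norm(e2), 1.0):
        raise DegenerateGeometryError("clearance plane points are collinear")
    return c1, n / nn


def check_clearance(
    chain: DHChain,
    q_trajectory: np.ndarray,
    c1,
    acr_l,
    acr_r,
    head_point=None,
) -> tuple[bool, int | None]:
    """Check that J4 stays on the C1 (neck) side of the shoulder plane.

    The plane through C1 and the two acromion markers divides the space
    into a head region and a neck region; J4 must remain in the latter
    for every sample.  ``head_point`` marks the head side (defaults to
    the chain base origin being on the *neck* side, i.e. the head side is
    opposite the base).

    Returns ``(passed, first_violating_sample_or_None)``.
    """
    q_trajectory = np.atleast_2d(np.asarray(q_trajectory, dtype=float))
    point, normal = clearance_plane(c1, acr_l, acr_r)
    if head_point is None:
        base = chain.base.position
        neck_sign = np.sign(float((base - point) @ normal))
        if neck_sign == 0:
            raise DegenerateGeometryError(
                "cannot orient clearance plane from the chain base"
            )
    else:
        head_sign = np.sign(float((np.asarray(head_point) - point) @ normal))
        if head_sign == 0:
            raise DegenerateGeometryError(
                "head reference point lies on the clearance plane"
            )
        neck_sign = -head_sign
    j4 = point_on_chain_batch(chain, q_trajectory, 4)
    side = np.sign((j4 - point) @ normal)
    bad = np.flatnonzero(side != neck_sign)
    if bad.size:
        return False, int(bad[0])
    return True, None


def derive_joint_limits(
    q_trajectories: Sequence[np.ndarray], margin: float
) -> np.ndarray:
    """Per-joint [min - margin, max + margin] over observed trajectories."""
    if margin < 0:
        raise InvalidInputError("margin must be non-negative")
    trajs = [np.atleast_2d(np.asarray(t, dtype=float)) for t in q_trajectories]
    if not trajs:
        raise InvalidInputError("need at least one joint trajectory")
    stacked = np.vstack(trajs)
    if stacked.shape[1] != 6:
        raise InvalidInputError("joint trajectories must have 6 columns")
    return np.column_stack(
        [stacked.min(axis=0) - margin, stacked.max(axis=0) + margin]
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_marker_csv(trial: MarkerTrial, path: str | Path) -> None:
    data = {"time_s": trial.time_s}
    for label in MARKER_LABELS:
        for j, ax in enumerate("xyz"):
            data[f"{label}_{ax}_mm"] = trial.markers[label][:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_marker_csv(path: str | Path, kind: str) -> MarkerTrial:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise SchemaError(f"{path}: missing column 'time_s'")
    markers = {}
    for label in MARKER_LABELS:
        cols = [f"{label}_{ax}_mm" for ax in "xyz"]
        for c in cols:
            if c not in df.columns:
                raise SchemaError(f"{path}: missing column {c!r}")
        markers[label] = df[cols].to_numpy(dtype=float)
    return MarkerTrial(kind=kind, time_s=df["time_s"].to_numpy(dtype=float),
                       markers=markers)
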