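"""Workspace analysis: frames, clouds, sphere fit, DH search, clearance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from neckbrace.chain import default_chain, forward_kinematics_batch
from neckbrace.design import (
    MARKER_LABELS,
    ClearanceSpec,
    MarkerTrial,
    WorkspaceCloud,
    build_reference_frame,
    check_clearance,
    clearance_plane,
    derive_joint_limits,
    farthest_point_subsample,
    fit_sphere,
    read_marker_csv,
    search_dh_parameters,
    to_trunk_frame,
    trunk_frames,
    write_marker_csv,
)
from neckbrace.errors import (
    DegenerateGeometryError,
    InvalidInputError,
    SchemaError,
)

CANONICAL = {
    "C7": [0.0, 0.0, 0.0],
    "CHEST": [140.0, 0.0, 0.0],
    "ACR_L": [0.0, 180.0, -10.0],
    "ACR_R": [0.0, -180.0, -10.0],
    "C1": [30.0, 0.0, 110.0],
    "HEAD_TOP": [0.0, 0.0, 266.0],
    "HEAD_L": [0.0, 85.0, 190.0],
    "HEAD_R": [0.0, -85.0, 190.0],
}


def make_static_trial(n=5, transform=None):
    markers = {}
    for label, pos in CANONICAL.items():
        p = np.tile(np.asarray(pos, dtype=float), (n, 1))
        if transform is not None:
            R, t = transform
            p = p @ R.T + t
        markers[label] = p
    return MarkerTrial(kind="static", time_s=np.arange(n) / 200.0, markers=markers)


class TestReferenceFrames:
    def test_canonical_markers_give_identity(self):
        trunk, head = build_reference_frame(make_static_trial())
        np.testing.assert_allclose(trunk.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(trunk.position, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(head.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(head.position, [0, 0, 266.0], atol=1e-12)

    def test_rigid_transform_equivariance(self, rng):
        R = Rotation.random(random_state=7).as_matrix()
        t = rng.uniform(-100, 100, 3)
        trunk0, head0 = build_reference_frame(make_static_trial())
        trunk1, head1 = build_reference_frame(make_static_trial(transform=(R, t)))
        np.testing.assert_allclose(trunk1.rotation, R @ trunk0.rotation, atol=1e-9)
        np.testing.assert_allclose(trunk1.position, R @ trunk0.position + t, atol=1e-9)
        np.testing.assert_allclose(head1.rotation, R @ head0.rotation, atol=1e-9)
        np.testing.assert_allclose(head1.position, R @ head0.position + t, atol=1e-9)

    def test_missing_label_is_schema_error(self):
        markers = {
            k: np.tile(np.asarray(v), (3, 1))
            for k, v in CANONICAL.items()
            if k != "HEAD_TOP"
        }
        with pytest.raises(SchemaError, match="HEAD_TOP"):
            MarkerTrial(kind="static", time_s=np.arange(3) / 200.0, markers=markers)

    def test_collinear_markers_degenerate(self):
        bad = dict(CANONICAL)
        bad["ACR_L"] = [280.0, 0.0, 0.0]  # collinear with C7->CHEST
        bad["ACR_R"] = [70.0, 0.0, 0.0]
        markers = {k: np.tile(np.asarray(v), (3, 1)) for k, v in bad.items()}
        trial = MarkerTrial(kind="static", time_s=np.arange(3) / 200.0, markers=markers)
        with pytest.raises(DegenerateGeometryError):
            build_reference_frame(trial)


class TestToTrunkFrame:
    def test_point_on_c7_maps_to_origin(self, rng):
        n = 40
        tp = rng.uniform(-50, 50, (n, 3))
        tR = Rotation.random(n, random_state=3).as_matrix()
        cloud = to_trunk_frame(tp, tp, tR)
        np.testing.assert_allclose(cloud.points, 0.0, atol=1e-9)

    def test_invariant_to_common_rigid_motion(self, rng):
        n = 30
        pts = rng.uniform(-100, 100, (n, 3))
        tp = rng.uniform(-20, 20, (n, 3))
        tR = Rotation.random(n, random_state=5).as_matrix()
        base = to_trunk_frame(pts, tp, tR).points
        R = Rotation.random(random_state=11).as_matrix()
        t = np.array([10.0, -22.0, 5.0])
        moved = to_trunk_frame(
            pts @ R.T + t, tp @ R.T + t, R @ tR
        ).points
        np.testing.assert_allclose(moved, base, atol=1e-9)

    def test_static_point_under_trunk_rotation(self, rng):
        """Fixed lab point under pure trunk rotation traces the inverse."""
        n = 25
        point = np.array([50.0, 30.0, 100.0])
        tR = Rotation.random(n, random_state=9).as_matrix()
        tp = np.zeros((n, 3))
        out = to_trunk_frame(np.tile(point, (n, 1)), tp, tR).points
        expected = np.einsum("nji,j->ni", tR, point)  # R^T @ point
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_sample_count_mismatch(self, rng):
        with pytest.raises(InvalidInputError):
            to_trunk_frame(
                rng.uniform(size=(5, 3)),
                rng.uniform(size=(4, 3)),
                np.tile(np.eye(3), (4, 1, 1)),
            )


def sphere_points(center, radius, n, rng=None, noise=0.0):
    if rng is None:
        rng = np.random.default_rng(0)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = np.asarray(center) + radius * v
    if noise:
        pts = pts + noise * rng.standard_normal((n, 3))
    return pts


class TestSphereFit:
    def test_exact_unit_sphere(self):
        pts = sphere_points([0, 0, 0], 1.0, 20)
        fit = fit_sphere(WorkspaceCloud(pts))
        np.testing.assert_allclose(fit.center, 0.0, atol=1e-9)
        assert fit.radius == pytest.approx(1.0, abs=1e-9)
        assert fit.rms_residual < 1e-9

    def test_noisy_recovery_within_1mm(self):
        rng = np.random.default_rng(42)
        pts = sphere_points([10, 20, 30], 90.0, 500, rng=rng, noise=1.0)
        fit = fit_sphere(WorkspaceCloud(pts))
        assert np.linalg.norm(fit.center - [10, 20, 30]) < 1.0
        assert abs(fit.radius - 90.0) < 1.0

    def test_coplanar_cloud_degenerate(self, rng):
        pts = rng.uniform(-50, 50, (100, 3))
        pts[:, 2] = 0.0
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(WorkspaceCloud(pts))

    def test_too_few_points(self):
        with pytest.raises(InvalidInputError):
            fit_sphere(WorkspaceCloud(np.zeros((3, 3))))

    @pytest.mark.parametrize("n", [50, 500, 5000])
    def test_consistency_error_shrinks(self, n):
        """Center error stays bounded by ~sigma/sqrt(n) growth."""
        rng = np.random.default_rng(n)
        pts = sphere_points([5, -5, 15], 80.0, n, rng=rng, noise=1.0)
        fit = fit_sphere(WorkspaceCloud(pts))
        err = np.linalg.norm(fit.center - [5, -5, 15])
        assert err < 10.0 / np.sqrt(n) + 0.3


class TestSearch:
    def test_planted_chain_recovered(self, chain, rng):
        q = rng.uniform(-1.0, 1.0, (150, 6))
        pts = forward_kinematics_batch(chain, q)[:, :3, 3]
        cloud = WorkspaceCloud(pts)
        grid = {
            ("a", 2): [chain.a[1] - 40.0, chain.a[1]],
            ("d", 4): [chain.d[3], chain.d[3] + 30.0],
        }
        results = search_dh_parameters(
            cloud, chain, grid, n_eval=40, tol_reach_mm=2.0
        )
        found = [
            r
            for r in results
            if r.params["a2"] == pytest.approx(chain.a[1])
            and r.params["d4"] == pytest.approx(chain.d[3])
        ]
        assert found and found[0].reach_fraction == 1.0

    def test_monotone_in_grid(self, chain, rng):
        q = rng.uniform(-0.8, 0.8, (60, 6))
        cloud = WorkspaceCloud(forward_kinematics_batch(chain, q)[:, :3, 3])
        small = {("a", 2): [chain.a[1]]}
        large = {("a", 2): [chain.a[1] - 50.0, chain.a[1]]}
        r_small = search_dh_parameters(cloud, chain, small, n_eval=25)
        r_large = search_dh_parameters(cloud, chain, large, n_eval=25)
        small_keys = {tuple(sorted(r.params.items())) for r in r_small}
        large_keys = {tuple(sorted(r.params.items())) for r in r_large}
        assert small_keys <= large_keys

    def test_all_candidates_too_short(self, chain):
        far = np.array([[400.0, 0.0, 300.0], [0.0, 400.0, 300.0]])
        tiny = chain.with_params(
            a=[5.0, 5.0, 0, 0, 0, 0], d=[0, 0, 5.0, 5.0, 0, 10.0]
        )
        grid = {("a", 2): [4.0, 5.0]}
        assert search_dh_parameters(WorkspaceCloud(far), tiny, grid, n_eval=2) == []

    def test_empty_grid_invalid(self, chain):
        with pytest.raises(InvalidInputError):
            search_dh_parameters(
                WorkspaceCloud(np.zeros((5, 3))), chain, {}
            )

    def test_sorted_by_total_length(self, chain, rng):
        q = rng.uniform(-0.5, 0.5, (40, 6))
        cloud = WorkspaceCloud(forward_kinematics_batch(chain, q)[:, :3, 3])
        grid = {("a", 2): [chain.a[1], chain.a[1] + 10.0]}
        results = search_dh_parameters(cloud, chain, grid, n_eval=15)
        lengths = [r.total_link_length for r in results]
        assert lengths == sorted(lengths)

    def test_farthest_point_subsample(self, rng):
        pts = rng.uniform(-10, 10, (200, 3))
        sub = farthest_point_subsample(pts, 20)
        assert sub.shape == (20, 3)
        assert farthest_point_subsample(pts, 500).shape == (200, 3)


class TestClearance:
    C1 = np.array([30.0, 0.0, 110.0])
    ACR_L = np.array([0.0, 180.0, -10.0])
    ACR_R = np.array([0.0, -180.0, -10.0])
    HEAD = np.array([0.0, 0.0, 266.0])

    def test_plane_normal_orthogonal_to_edges(self):
        point, normal = clearance_plane(self.C1, self.ACR_L, self.ACR_R)
        assert abs(normal @ (self.ACR_L - self.C1)) < 1e-12
        assert abs(normal @ (self.ACR_R - self.C1)) < 1e-12
        assert np.linalg.norm(normal) == pytest.approx(1.0)

    def test_neutral_j4_passes(self, chain):
        ok, bad = check_clearance(
            chain, np.zeros((10, 6)), self.C1, self.ACR_L, self.ACR_R,
            head_point=self.HEAD,
        )
        assert ok and bad is None

    def test_violation_reports_first_sample(self, chain):
        # proximal joints folded backward push J4 across the plane
        crossing = np.array([-0.801, -0.309, -1.887, -1.503, 0.682, 0.589])
        q = np.zeros((8, 6))
        q[5] = crossing
        q[6] = crossing
        ok, bad = check_clearance(
            chain, q, self.C1, self.ACR_L, self.ACR_R, head_point=self.HEAD
        )
        assert not ok
        assert bad == 5

    def test_collinear_plane_points(self, chain):
        with pytest.raises(DegenerateGeometryError):
            check_clearance(
                chain, np.zeros((1, 6)),
                [0, 0, 0], [1, 0, 0], [2, 0, 0],
            )


class TestJointLimits:
    def test_constant_trajectory(self):
        traj = np.full((50, 6), 0.3)
        lim = derive_joint_limits([traj], margin=0.1)
        np.testing.assert_allclose(lim[:, 0], 0.2, atol=1e-12)
        np.testing.assert_allclose(lim[:, 1], 0.4, atol=1e-12)

    def test_sinusoid_amplitude(self):
        t = np.linspace(0, 2 * np.pi, 4001)
        traj = np.column_stack([0.7 * np.sin(t)] * 6)
        lim = derive_joint_limits([traj], margin=0.05)
        np.testing.assert_allclose(lim[:, 1], 0.75, atol=1e-5)
        np.testing.assert_allclose(lim[:, 0], -0.75, atol=1e-5)

    def test_empty_input_error(self):
        with pytest.raises(InvalidInputError):
            derive_joint_limits([], margin=0.1)

    def test_negative_margin_error(self):
        with pytest.raises(InvalidInputError):
            derive_joint_limits([np.zeros((3, 6))], margin=-0.1)


class TestMarkerCSV:
    def test_round_trip(self, tmp_path):
        trial = make_static_trial(n=7)
        path = tmp_path / "markers.csv"
        write_marker_csv(trial, path)
        loaded = read_marker_csv(path, kind="static")
        for label in MARKER_LABELS:
            np.testing.assert_allclose(
                loaded.markers[label], trial.markers[label], atol=1e-9
            )

    def test_missing_column(self, tmp_path):
        trial = make_static_trial(n=4)
        path = tmp_path / "markers.csv"
        write_marker_csv(trial, path)
        import pandas as pd

        df = pd.read_csv(path).drop(columns=["HEAD_L_y_mm"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="HEAD_L_y_mm"):
            read_marker_csv(path, kind="static")
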