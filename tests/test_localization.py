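"""Absolute transform, background subtraction, clustering and tracking."""

import math

import numpy as np
import pytest

from lidarhar.footprints import footprint_at
from lidarhar.lidar import (LidarConfig, NoiseConfig, cast_scan,
                            interpolate_scan)
from lidarhar.localization import (Cluster, LocalizationConfig, Track,
                                   cluster_candidates, localize_stream,
                                   select_subject, subtract_background,
                                   to_absolute)
from lidarhar.lidar import Scan
from lidarhar.world import Pose2D, plan_robot_path

CFG = LocalizationConfig()
NOISELESS = NoiseConfig(0, 0, 0, 0)


def _scan_from(pose, r, theta):
    return Scan(t=0.0, pose=pose, r=np.asarray(r, float),
                theta=np.asarray(theta, float), gridded=False)


class TestToAbsolute:
    @pytest.mark.parametrize("pose,point,expected", [
        ((0, 0, 0), (1.0, 0.0), (1.0, 0.0)),
        ((2, 3, 0), (2.0, math.pi / 2), (2.0, 5.0)),
        ((0, 0, math.pi / 2), (1.0, 0.0), (0.0, 1.0)),
    ])
    def test_examples(self, pose, point, expected):
        scan = _scan_from(Pose2D(*pose), [point[0]], [point[1]])
        pts, _ = to_absolute(scan)
        assert pts[0] == pytest.approx(expected, abs=1e-12)

    def test_round_trip(self, rng):
        # inverse of projecting world points into the sensor frame
        for _ in range(50):
            pose = Pose2D(*rng.uniform(0, 6, 2), rng.uniform(0, 2 * np.pi))
            world = rng.uniform(0, 6, (20, 2))
            d = world - [pose.x, pose.y]
            r = np.hypot(d[:, 0], d[:, 1])
            theta = (np.arctan2(d[:, 1], d[:, 0]) - pose.heading)
            pts, _ = to_absolute(_scan_from(pose, r, theta))
            assert np.abs(pts - world).max() < 1e-9


class TestBackgroundSubtraction:
    def test_wall_points_removed(self, empty_room):
        pts = np.array([[3.0, 5.9], [0.05, 3.0], [5.95, 0.05]])
        assert not subtract_background(pts, empty_room, 0.2).any()

    def test_open_space_point_kept(self, empty_room):
        pts = np.array([[3.0, 3.0]])
        assert subtract_background(pts, empty_room, 0.2).all()

    def test_threshold_boundary(self, empty_room):
        near_wall = np.array([[3.0, 5.8]])     # ~0.1 m from the wall
        clear = np.array([[3.0, 5.3]])         # ~0.6 m from the wall
        assert not subtract_background(near_wall, empty_room, 0.2).any()
        assert subtract_background(clear, empty_room, 0.2).all()

    def test_empty_room_scans_yield_nothing(self, obstacle_room):
        # noiseless scans of the bare room from a moving sensor are fully
        # explained by the map, for every pose along the sweep
        traj = plan_robot_path(obstacle_room, 0.2, 5.0, 20.0, seed=0)
        for pose in traj.poses[::10]:
            scan = interpolate_scan(
                cast_scan(obstacle_room, [], pose, LidarConfig()))
            pts, _ = to_absolute(scan)
            assert not subtract_background(pts, obstacle_room, 0.2).any()


def brute_force_dbscan(pts, eps, min_pts):
    """O(n^2) reference DBSCAN: returns (labels for cores, core mask,
    border candidate label sets, noise mask)."""
    n = len(pts)
    d = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                 pts[:, None, 1] - pts[None, :, 1])
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_pts
    labels = -np.ones(n, dtype=int)
    cur = 0
    for i in range(n):
        if core[i] and labels[i] < 0:
            stack = [i]
            labels[i] = cur
            while stack:
                j = stack.pop()
                for k in range(n):
                    if core[k] and labels[k] < 0 and neigh[j, k]:
                        labels[k] = cur
                        stack.append(k)
            cur += 1
    border_opts = {}
    noise = np.zeros(n, bool)
    for i in range(n):
        if core[i]:
            continue
        opts = {labels[j] for j in range(n) if core[j] and neigh[i, j]}
        if opts:
            border_opts[i] = opts
        else:
            noise[i] = True
    return labels, core, border_opts, noise


class TestClustering:
    def test_fewer_than_min_pts_all_noise(self):
        pts = np.array([[0.0, 0.0], [10.0, 10.0]])
        assert cluster_candidates(pts, 0.3, 3) == []

    def test_two_blobs_two_clusters(self, rng):
        a = rng.normal([1, 1], 0.05, (10, 2))
        b = rng.normal([3, 3], 0.05, (10, 2))
        clusters = cluster_candidates(np.vstack([a, b]), 0.3, 3)
        assert len(clusters) == 2

    def test_centroid_is_member_mean(self, rng):
        pts = rng.normal([2, 2], 0.05, (15, 2))
        (cl,) = cluster_candidates(pts, 0.5, 3)
        assert cl.centroid == pytest.approx(cl.points.mean(axis=0))

    def test_matches_brute_force_oracle(self, rng):
        from sklearn.cluster import DBSCAN
        for trial in range(200):
            n = int(rng.integers(5, 81))
            pts = rng.uniform(0, 4, (n, 2))
            eps = float(rng.uniform(0.15, 0.6))
            mp = int(rng.integers(2, 6))
            sk = DBSCAN(eps=eps, min_samples=mp).fit_predict(pts)
            labels, core, border_opts, noise = brute_force_dbscan(
                pts, eps, mp)
            # noise agrees exactly
            assert np.array_equal(sk == -1, noise)
            # core partition agrees up to label permutation
            mapping = {}
            for i in np.nonzero(core)[0]:
                assert sk[i] >= 0
                if labels[i] in mapping:
                    assert mapping[labels[i]] == sk[i]
                else:
                    mapping[labels[i]] = sk[i]
            assert len(set(mapping.values())) == len(mapping)
            # border points join one of their admissible clusters
            for i, opts in border_opts.items():
                assert sk[i] in {mapping[o] for o in opts}


class TestTracking:
    def _cluster(self, x, y, n=5):
        pts = np.tile([x, y], (n, 1))
        return Cluster(points=pts, centroid=np.array([x, y], float))

    def test_initialization_picks_largest(self):
        track = Track()
        small = self._cluster(1, 1, n=3)
        big = self._cluster(4, 4, n=8)
        obs = select_subject([small, big], track, CFG, 0.0,
                             np.array([3.0, 3.0]))
        assert obs.status == "detected"
        assert obs.location == pytest.approx([4, 4])

    def test_gating_prefers_nearby_cluster(self):
        track = Track(location=np.array([1.0, 1.0]))
        near = self._cluster(1.3, 1.0)
        far = self._cluster(4.0, 4.0, n=20)
        obs = select_subject([near, far], track, CFG, 0.0,
                             np.array([3.0, 3.0]))
        assert obs.location == pytest.approx([1.3, 1.0])

    def test_out_of_gate_clusters_trigger_coasting(self):
        track = Track(location=np.array([1.0, 1.0]))
        far = self._cluster(4.0, 4.0)
        obs = select_subject([far], track, CFG, 0.0, np.array([3.0, 3.0]))
        assert obs.status == "coasting"
        assert obs.location == pytest.approx([1.0, 1.0])

    def test_track_lost_after_t_lost_ticks(self):
        cfg = LocalizationConfig(t_lost=3)
        track = Track(location=np.array([1.0, 1.0]))
        statuses = [select_subject([], track, cfg, float(t),
                                   np.array([3.0, 3.0])).status
                    for t in range(5)]
        assert statuses == ["coasting"] * 3 + ["lost", "lost"]


class TestStream:
    def _standing_scans(self, room, n=100, noise=NOISELESS, seed=0,
                        human_xy=(2.0, 2.5), interrupt=None):
        from lidarhar.lidar import apply_noise
        rng = np.random.default_rng(seed)
        prims = footprint_at("standing", 0.0, Pose2D(*human_xy, 0.3), 0.10)
        scans = []
        for k in range(n):
            ang = 2 * np.pi * k / n
            pose = Pose2D(4.0 + 0.8 * np.cos(ang), 3.0 + 0.8 * np.sin(ang),
                          ang)
            p = [] if interrupt and k in interrupt else prims
            s = cast_scan(room, p, pose, LidarConfig(), t=k * 0.05)
            scans.append(interpolate_scan(apply_noise(s, noise, rng)))
        return scans

    def test_empty_room_all_lost(self, empty_room):
        scans = self._standing_scans(empty_room, n=40, interrupt=range(40))
        obs = localize_stream(scans, empty_room)
        assert all(o.status == "lost" for o in obs)
        assert all(len(o.subject_points) == 0 for o in obs)

    def test_standing_centroid_accuracy(self, empty_room):
        scans = self._standing_scans(empty_room, n=200)
        obs = localize_stream(scans, empty_room)
        det = [o for o in obs if o.status == "detected"]
        assert len(det) >= 190
        errs = [np.linalg.norm(o.location - [2.0, 2.5]) for o in det]
        assert np.mean(errs) <= 0.2

    def test_coasting_through_occlusion(self, empty_room):
        cfg = LocalizationConfig(t_lost=40)
        scans = self._standing_scans(empty_room, n=60,
                                     interrupt=set(range(25, 35)))
        obs = localize_stream(scans, empty_room, cfg)
        assert all(o.status == "coasting" for o in obs[25:35])
        assert obs[40].status == "detected"

    def test_subject_recall_under_noise(self, empty_room):
        from lidarhar.lidar import PROV_HUMAN
        scans = self._standing_scans(empty_room, n=100,
                                     noise=NoiseConfig(), seed=3)
        obs = localize_stream(scans, empty_room)
        recalls = []
        for s, o in zip(scans, obs):
            n_human = int((s.provenance == PROV_HUMAN).sum())
            if o.status != "detected" or n_human == 0:
                continue
            got = int((o.provenance == PROV_HUMAN).sum())
            recalls.append(got / n_human)
        assert len(recalls) >= 90
        assert np.mean(recalls) >= 0.9

    def test_unordered_scans_rejected(self, empty_room):
        scans = self._standing_scans(empty_room, n=5)
        scans[1], scans[3] = scans[3], scans[1]
        with pytest.raises(ValueError):
            localize_stream(scans, empty_room)
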