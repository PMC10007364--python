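"""Metrics engine, parameter-count report and the sensor comparison."""

import numpy as np
import pytest

from lidarhar.classifier import ArchitectureSpec
from lidarhar.evaluation import (REFERENCE_CONFUSION, complexity_report,
                                 confusion, nominal_conv_params,
                                 nominal_dense_params, overall_metrics,
                                 per_class_metrics, rank_fixed_sensors,
                                 round_pct)
from lidarhar.world import ACTIVITIES

#: Published per-class results table (accuracy / precision / recall / F1 in
#: percent) that must be reproducible from REFERENCE_CONFUSION.  The
#: "accuracy" column of that table is the per-class recall.
REFERENCE_TABLE = {
    "crawling": (88.3, 91.2, 88.3, 89.7),
    "falling down": (81.2, 88.5, 81.2, 84.7),
    "getting up": (93.4, 90.0, 93.4, 91.7),
    "lying down": (99.0, 99.3, 99.0, 99.2),
    "running": (73.0, 77.5, 73.0, 75.2),
    "sitting": (93.9, 95.1, 93.9, 94.5),
    "standing": (97.4, 95.3, 97.4, 96.3),
    "walking": (83.4, 87.0, 83.4, 85.2),
    "unsteady walk": (89.1, 85.1, 89.1, 87.0),
}


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.arange(9).repeat(3)
        cm = confusion(y, y)
        assert np.array_equal(cm, np.diag(np.bincount(y)))

    def test_single_miss(self):
        cm = confusion([0, 0, 1], [0, 1, 1], n_classes=2)
        assert cm[0, 1] == 1 and cm[0, 0] == 1 and cm[1, 1] == 1

    def test_row_sums_equal_true_histogram(self, rng):
        true = rng.integers(0, 9, 1000)
        pred = rng.integers(0, 9, 1000)
        cm = confusion(true, pred)
        assert np.array_equal(cm.sum(axis=1), np.bincount(true, minlength=9))

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 9], [0, 0])


class TestReferenceReproduction:
    def test_full_table_reproduced_to_one_decimal(self):
        report = per_class_metrics(REFERENCE_CONFUSION)
        for name, (acc, prec, rec, f1) in REFERENCE_TABLE.items():
            m = report.by_name(name)
            assert round_pct(m.recall) == acc, name
            assert round_pct(m.precision) == prec, name
            assert round_pct(m.f1) == f1, name

    def test_overall_row(self):
        o = overall_metrics(REFERENCE_CONFUSION)
        for key in ("overall_accuracy", "micro_precision", "micro_recall",
                    "micro_f1"):
            assert round_pct(o[key]) == 91.3


class TestMetrics:
    def test_diagonal_matrix_is_perfect(self):
        cm = np.diag([5, 3, 7])
        assert overall_metrics(cm)["overall_accuracy"] == 1.0

    def test_micro_identity_on_random_matrices(self, rng):
        for _ in range(100):
            cm = rng.integers(0, 50, (6, 6))
            if cm.sum() == 0:
                continue
            o = overall_metrics(cm)
            assert o["micro_precision"] == pytest.approx(
                o["overall_accuracy"])
            assert o["micro_recall"] == pytest.approx(o["overall_accuracy"])

    def test_degenerate_single_class_flagged(self):
        cm = np.zeros((3, 3), dtype=int)
        cm[1, 1] = 10
        report = per_class_metrics(cm, class_names=("a", "b", "c"))
        assert report.by_name("b").recall == 1.0
        assert report.by_name("a").degenerate
        assert report.by_name("a").f1 == 0.0

    def test_metrics_bounded(self, rng):
        cm = rng.integers(0, 30, (9, 9))
        report = per_class_metrics(cm)
        for m in report.per_class:
            for v in (m.accuracy, m.precision, m.recall, m.f1):
                assert 0.0 <= v <= 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            overall_metrics(np.zeros((9, 9), dtype=int))


class TestComplexityReport:
    def test_nominal_formula_examples(self):
        assert nominal_conv_params(60, 60, 1, 32) == 230_400
        assert nominal_dense_params(9, 100) == 909

    def test_v1_report_carries_both_conventions(self):
        rep = complexity_report(ArchitectureSpec("v1"), (40, 60, 60, 1))
        by_layer = {d["layer"]: d for d in rep.layers}
        assert by_layer["conv1"]["standard"] == 320
        assert by_layer["conv1"]["nominal"] == 230_400
        feat = 30 * 30 * 32
        assert by_layer["lstm"]["nominal"] == \
            feat * 40 + 40 * 100 + 40 + 100
        assert by_layer["lstm"]["standard"] == 4 * ((feat + 40) * 40 + 40)
        assert by_layer["dense2"]["nominal"] == 909
        assert rep.nominal_total == sum(d["nominal"] for d in rep.layers)
        assert rep.standard_total == sum(d["standard"] for d in rep.layers)

    def test_standard_total_matches_built_model(self):
        from lidarhar.classifier import build_model
        rep = complexity_report(ArchitectureSpec("v1"), (40, 60, 60, 1), 9)
        model = build_model(ArchitectureSpec("v1"), (40, 60, 60, 1), 9)
        assert rep.standard_total == model.n_params


@pytest.fixture(scope="module")
def occlusion_run():
    """A fall hidden from the corner sensor by a slab obstacle, while
    the mobile robot drives past with line of sight."""
    from lidarhar.lidar import LidarConfig, NoiseConfig, run_scenario
    from lidarhar.world import (ActivityScript, Pose2D, RoomMap,
                                Trajectory, animate_human)
    kind = np.zeros((60, 60), dtype=np.uint8)
    kind[0, :] = kind[-1, :] = kind[:, 0] = kind[:, -1] = 1
    kind[28:32, 8:30] = 2          # slab between corner and subject
    room = RoomMap(kind=kind, resolution=0.1, dlength=6, dwidth=6)
    script = ActivityScript([
        ("standing", 2.0), ("falling down", 2.0), ("lying down", 4.0),
        ("getting up", 2.0), ("standing", 2.0)])
    truth = animate_human(script, room, 1.0, 10.0, seed=0,
                          start=(2.0, 4.5))
    n = len(truth)
    poses = [Pose2D(3.5, 4.5, np.pi)] * n      # robot nearby, LoS
    traj = Trajectory(timestamps=truth.timestamps, poses=poses)
    fixed = {"corner": Pose2D(0.4, 0.4, np.pi / 4)}  # blocked by slab
    return run_scenario(room, truth, traj, LidarConfig(scan_rate=10.0),
                        NoiseConfig(), seed=0, fixed_poses=fixed)


class TestSensorComparison:
    def test_mobile_beats_blocked_corner_on_falls(self, occlusion_run):
        from lidarhar.classifier import TrainConfig
        from lidarhar.evaluation import compare_sensors
        from lidarhar.localization import LocalizationConfig
        from lidarhar.representation import RepresentationConfig
        rep = RepresentationConfig(window_len=20, stride=5)
        reports = compare_sensors(occlusion_run, LocalizationConfig(),
                                  rep, TrainConfig(epochs=8, seed=0))
        mob = reports["mobile"].by_name("falling down").recall
        cor = reports["corner"].by_name("falling down").recall
        assert mob >= cor
        assert reports["mobile"].confusion_matrix.sum() > 0
        assert reports["corner"].confusion_matrix.sum() == 0

    def test_identical_streams_identical_reports(self, occlusion_run):
        from lidarhar.classifier import TrainConfig
        from lidarhar.evaluation import compare_sensors
        from lidarhar.localization import LocalizationConfig
        from lidarhar.representation import RepresentationConfig
        rep = RepresentationConfig(window_len=20, stride=10)
        kw = dict(loc_config=LocalizationConfig(), repr_config=rep,
                  train_config=TrainConfig(epochs=2, seed=0))
        a = compare_sensors(occlusion_run, **kw)
        b = compare_sensors(occlusion_run, **kw)
        for sid in a:
            assert np.array_equal(a[sid].confusion_matrix,
                                  b[sid].confusion_matrix)

    def test_report_schema_and_ranking(self, occlusion_run):
        from lidarhar.classifier import TrainConfig
        from lidarhar.evaluation import compare_sensors
        from lidarhar.localization import LocalizationConfig
        from lidarhar.representation import RepresentationConfig
        rep = RepresentationConfig(window_len=20, stride=10)
        reports = compare_sensors(occlusion_run, LocalizationConfig(), rep,
                                  TrainConfig(epochs=1, seed=0))
        r = reports["mobile"]
        assert set(r.as_dict()["overall"]) == {"accuracy", "precision",
                                               "recall", "f1"}
        best, worst = rank_fixed_sensors(reports)
        assert best == worst == "corner"
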