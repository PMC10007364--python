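"""Evaluation: confusion matrices, per-class and micro-averaged metrics,
parameter-count reports, and the fixed-vs-mobile sensor comparison harness.

Per class ``c`` on a confusion matrix ``cm`` (rows = true, columns =
predicted): TP = cm[c,c], FN = row - TP, FP = col - TP, TN = rest;
accuracy = (TP+TN)/(TP+TN+FP+FN), precision = TP/(TP+FP), recall =
TP/(TP+FN), F1 = 2PR/(P+R).  The overall row is micro-averaged: pooling
TP/FP/FN over classes makes precision, recall and accuracy coincide for
single-label multi-class problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .world import ACTIVITIES, N_CLASSES

#: Published reference confusion matrix (test set) of the mobile-Lidar
#: activity-recognition system this package re-implements at desk scale;
#: rows = true class, columns = predicted, in canonical class order
#: (crawling, falling down, getting up, lying down, running, sitting,
#: standing, walking, unsteady walk).  Used to validate the metrics engine
#: by reproducing the published per-class table from raw counts.
REFERENCE_CONFUSION = np.array([
    [83,   2,   5,   2,   0,   0,   0,   0,   2],
    [5,   69,   1,   2,   0,   5,   1,   2,   0],
    [1,    3, 341,   1,   0,   5,   5,   1,   8],
    [1,    2,   3, 893,   0,   2,   0,   0,   1],
    [0,    0,   2,   0, 203,   1,   1,  49,  22],
    [0,    1,   5,   1,   1, 371,   5,   4,   7],
    [1,    0,   4,   0,   2,   0, 778,   2,  12],
    [0,    1,   5,   0,  44,   1,  15, 615,  56],
    [0,    0,  13,   0,  12,   5,  11,  34, 615],
], dtype=np.int64)


def round_pct(x: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up, for table-style reporting."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(100.0 * x)).quantize(q, rounding=ROUND_HALF_UP))


def confusion(true_labels, pred_labels, n_classes: int = N_CLASSES
              ) -> np.ndarray:
    true_labels = np.asarray(true_labels, dtype=np.int64)
    pred_labels = np.asarray(pred_labels, dtype=np.int64)
    if true_labels.shape != pred_labels.shape:
        raise ValueError("label arrays differ in length")
    if len(true_labels) and (
            true_labels.min() < 0 or true_labels.max() >= n_classes
            or pred_labels.min() < 0 or pred_labels.max() >= n_classes):
        raise ValueError("label out of range")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (true_labels, pred_labels), 1)
    return cm


@dataclass
class ClassMetrics:
    name: str
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    degenerate: bool = False    # a zero denominator was flagged


@dataclass
class EvaluationReport:
    confusion_matrix: np.ndarray
    per_class: list[ClassMetrics]
    overall_accuracy: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    class_names: tuple[str, ...] = tuple(ACTIVITIES)

    def by_name(self, name: str) -> ClassMetrics:
        for m in self.per_class:
            if m.name == name:
                return m
        raise KeyError(name)

    def as_dict(self) -> dict:
        return {
            "overall": {"accuracy": self.overall_accuracy,
                        "precision": self.micro_precision,
                        "recall": self.micro_recall,
                        "f1": self.micro_f1},
            "per_class": {m.name: {"accuracy": m.accuracy,
                                   "precision": m.precision,
                                   "recall": m.recall, "f1": m.f1}
                          for m in self.per_class},
            "confusion_matrix": self.confusion_matrix.tolist(),
        }

    def table(self) -> str:
        rows = [f"{'Activity':<16}{'Acc':>8}{'Prec':>8}{'Rec':>8}{'F1':>8}"]
        for m in self.per_class:
            rows.append(f"{m.name:<16}{round_pct(m.accuracy):>7}%"
                        f"{round_pct(m.precision):>7}%"
                        f"{round_pct(m.recall):>7}%"
                        f"{round_pct(m.f1):>7}%")
        rows.append(f"{'Overall':<16}{round_pct(self.overall_accuracy):>7}%"
                    f"{round_pct(self.micro_precision):>7}%"
                    f"{round_pct(self.micro_recall):>7}%"
                    f"{round_pct(self.micro_f1):>7}%")
        return "\n".join(rows)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def per_class_metrics(cm: np.ndarray,
                      class_names=tuple(ACTIVITIES)) -> EvaluationReport:
    """Per-class and micro-averaged metrics from a confusion matrix.

    Note: per-class *recall* (diagonal over row total) is the quantity many
    application tables label "accuracy"; this report carries both, with
    accuracy meaning (TP+TN)/total.
    """
    cm = np.asarray(cm, dtype=np.int64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    out: list[ClassMetrics] = []
    for c in range(cm.shape[0]):
        tp = int(cm[c, c])
        fn = int(cm[c].sum()) - tp
        fp = int(cm[:, c].sum()) - tp
        tn = total - tp - fn - fp
        acc = (tp + tn) / total
        prec, d1 = _safe_div(tp, tp + fp)
        rec, d2 = _safe_div(tp, tp + fn)
        f1, d3 = _safe_div(2 * prec * rec, prec + rec)
        name = class_names[c] if c < len(class_names) else str(c)
        out.append(ClassMetrics(name=name, tp=tp, tn=tn, fp=fp, fn=fn,
                                accuracy=acc, precision=prec, recall=rec,
                                f1=f1, degenerate=d1 or d2 or d3))
    overall = overall_metrics(cm)
    return EvaluationReport(confusion_matrix=cm, per_class=out,
                            class_names=tuple(class_names), **overall)


def overall_metrics(cm: np.ndarray) -> dict[str, float]:
    """Micro-averaged overall metrics: pooled TP/FP/FN, so precision =
    recall = accuracy for single-label classification."""
    cm = np.asarray(cm, dtype=np.int64)
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = int(np.trace(cm))
    fp = total - tp
    fn = total - tp
    acc = tp / total
    prec, _ = _safe_div(tp, tp + fp)
    rec, _ = _safe_div(tp, tp + fn)
    f1, _ = _safe_div(2 * prec * rec, prec + rec)
    return {"overall_accuracy": acc, "micro_precision": prec,
            "micro_recall": rec, "micro_f1": f1}


# ---------------------------------------------------------------------------
# parameter-count report


@dataclass
class ComplexityReport:
    """Two parameter-count conventions, side by side.

    ``nominal`` follows the simplified per-layer formulas used in the
    application literature for this architecture family:
        conv:  h * w * (n_prev_filters + 1) * n_filters
        lstm:  n_in * n_hidden + n_hidden * n_out + n_hidden + n_out
        dense: n_current * (n_previous + 1)
    ``standard`` is the usual trainable-parameter count
    (conv: (k*k*c_in + 1)*c_out; lstm: 4*((n_in + n_h)*n_h + n_h);
    dense: (n_in + 1)*n_out).  Both are always reported; neither silently
    replaces the other.
    """

    layers: list[dict]
    nominal_total: int
    standard_total: int


def nominal_conv_params(h: int, w: int, n_prev_filters: int,
                        n_filters: int) -> int:
    return h * w * (n_prev_filters + 1) * n_filters


def nominal_lstm_params(n_in: int, n_hidden: int, n_out: int) -> int:
    return n_in * n_hidden + n_hidden * n_out + n_hidden + n_out


def nominal_dense_params(n_current: int, n_previous: int) -> int:
    return n_current * (n_previous + 1)


def complexity_report(spec, input_shape: tuple[int, ...],
                      n_classes: int = N_CLASSES) -> ComplexityReport:
    """Layer-by-layer parameter counts for an ArchitectureSpec."""
    t, h, w, c = input_shape
    filters = spec.conv_filters()
    layers: list[dict] = []
    c_in = c
    hh, ww = h, w
    for i, n_f in enumerate(filters):
        layers.append({
            "layer": f"conv{i + 1}",
            "nominal": nominal_conv_params(hh, ww, c_in, n_f),
            "standard": (3 * 3 * c_in + 1) * n_f,
        })
        c_in = n_f
        if (len(filters) == 1) or (i % 2 == 1):
            hh, ww = hh // 2, ww // 2
    feat = hh * ww * c_in
    nh = spec.lstm_units
    layers.append({
        "layer": "lstm",
        "nominal": nominal_lstm_params(feat, nh, spec.dense_units),
        "standard": 4 * ((feat + nh) * nh + nh),
    })
    layers.append({
        "layer": "dense1",
        "nominal": nominal_dense_params(spec.dense_units, nh),
        "standard": (nh + 1) * spec.dense_units,
    })
    layers.append({
        "layer": "dense2",
        "nominal": nominal_dense_params(n_classes, spec.dense_units),
        "standard": (spec.dense_units + 1) * n_classes,
    })
    return ComplexityReport(
        layers=layers,
        nominal_total=sum(d["nominal"] for d in layers),
        standard_total=sum(d["standard"] for d in layers),
    )


# ---------------------------------------------------------------------------
# fixed-vs-mobile sensor comparison


def compare_sensors(run, loc_config, repr_config, train_config,
                    arch_spec=None, holdout: int = 2,
                    n_classes: int = N_CLASSES) -> dict[str, EvaluationReport]:
    """Run the identical downstream pipeline per sensor and report each.

    For every sensor stream in the scenario run: localize, rasterize, window,
    split windows into train/held-out (every ``holdout``-th window held out),
    train the classifier and evaluate on the held-out part.  Sensors whose
    stream yields no usable windows get an all-zero report.
    """
    from .classifier import ArchitectureSpec, build_model
    from .classifier import predict as clf_predict
    from .classifier import samples_to_arrays
    from .classifier import train as clf_train
    from .localization import localize_stream
    from .representation import frames_from_observations, make_windows

    arch_spec = arch_spec or ArchitectureSpec()
    reports: dict[str, EvaluationReport] = {}
    for sid, scans in run.scans.items():
        obs = localize_stream(scans, run.room, loc_config)
        frames = frames_from_observations(obs, repr_config)
        statuses = [o.status for o in obs]
        samples = make_windows(frames, run.truth.labels, statuses,
                               repr_config)
        if not samples:
            reports[sid] = _empty_report(n_classes)
            continue
        x, y = samples_to_arrays(samples)
        test_idx = np.arange(len(x)) % holdout == 0
        x_tr, y_tr = x[~test_idx], y[~test_idx]
        x_te, y_te = x[test_idx], y[test_idx]
        if len(x_tr) == 0 or len(x_te) == 0:
            x_tr = x_te = x
            y_tr = y_te = y
        model = build_model(arch_spec, x.shape[1:] + (1,), n_classes,
                            seed=train_config.seed)
        clf_train(model, x_tr, y_tr, train_config, spec=arch_spec)
        _, pred = clf_predict(model, x_te)
        reports[sid] = per_class_metrics(confusion(y_te, pred, n_classes))
    return reports


def _empty_report(n_classes: int) -> EvaluationReport:
    """All-zero report for a sensor stream that produced no usable windows."""
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    per = [ClassMetrics(name=ACTIVITIES[c] if c < len(ACTIVITIES) else str(c),
                        tp=0, tn=0, fp=0, fn=0, accuracy=0.0, precision=0.0,
                        recall=0.0, f1=0.0, degenerate=True)
           for c in range(n_classes)]
    return EvaluationReport(confusion_matrix=cm, per_class=per,
                            overall_accuracy=0.0, micro_precision=0.0,
                            micro_recall=0.0, micro_f1=0.0)


def rank_fixed_sensors(reports: dict[str, EvaluationReport]
                       ) -> tuple[str | None, str | None]:
    """(best, worst) fixed sensor ids by overall accuracy."""
    fixed = {k: v for k, v in reports.items() if k != "mobile"}
    if not fixed:
        return None, None
    best = max(fixed, key=lambda k: fixed[k].overall_accuracy)
    worst = min(fixed, key=lambda k: fixed[k].overall_accuracy)
    return best, worst
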