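"""The two time-distributed ConvLSTM architectures, training and inference.

Variant ``v1`` (for the coarse Boolean grid): one time-distributed 3x3
convolution with 32 filters + 2x2 max pooling, flattened per frame into an
LSTM with 40 cells, then dense layers of 100 and ``n_classes`` neurons.
Variant ``v2`` (for the high-resolution circle/ellipse images): three blocks
of two 3x3 convolutions each followed by 2x2 pooling, with filter counts
(64, 64, 32, 32, 32, 32), then the same LSTM/dense tail.  Hidden activations
are ReLU, the output is a softmax, the loss is categorical cross-entropy and
the optimizer is Adam.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .world import ACTIVITIES

V1_FILTERS = (32,)
V2_FILTERS = (64, 64, 32, 32, 32, 32)
LSTM_UNITS = 40
DENSE_UNITS = 100


@dataclass
class ArchitectureSpec:
    variant: str = "v1"                       # v1 (grid) | v2 (image)
    lstm_units: int = LSTM_UNITS
    dense_units: int = DENSE_UNITS

    def conv_filters(self) -> tuple[int, ...]:
        if self.variant == "v1":
            return V1_FILTERS
        if self.variant == "v2":
            return V2_FILTERS
        raise ValueError(f"unknown architecture variant {self.variant!r}")


@dataclass
class TrainConfig:
    """Desk-scale defaults; ``full_profile`` restores the full 500-epoch
    regime."""

    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    @classmethod
    def full_profile(cls, seed: int = 0) -> "TrainConfig":
        return cls(epochs=500, batch_size=16, learning_rate=1e-3, seed=seed)


@dataclass
class Checkpoint:
    spec: ArchitectureSpec
    input_shape: tuple[int, ...]              # (T, H, W, C)
    n_classes: int
    weights: dict[str, np.ndarray]
    classes: tuple[str, ...] = tuple(ACTIVITIES)
    history: list[dict] = field(default_factory=list)
    train_config: TrainConfig | None = None

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.weights)
        meta = {
            "spec": asdict(self.spec),
            "input_shape": list(self.input_shape),
            "n_classes": self.n_classes,
            "classes": list(self.classes),
            "history": self.history,
            "train_config": (asdict(self.train_config)
                             if self.train_config else None),
            "activations": {"hidden": "relu", "output": "softmax"},
            "loss": "categorical cross-entropy",
            "optimizer": "adam",
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as npz:
            weights = {k: npz[k] for k in npz.files}
        tc = meta.get("train_config")
        return cls(spec=ArchitectureSpec(**meta["spec"]),
                   input_shape=tuple(meta["input_shape"]),
                   n_classes=meta["n_classes"], weights=weights,
                   classes=tuple(meta["classes"]),
                   history=meta.get("history", []),
                   train_config=TrainConfig(**tc) if tc else None)

    def model(self, dtype=np.float32) -> nn.SequenceModel:
        m = build_model(self.spec, self.input_shape, self.n_classes,
                        seed=0, dtype=dtype)
        m.set_weights(self.weights)
        return m


def build_model(spec: ArchitectureSpec, input_shape: tuple[int, ...],
                n_classes: int, seed: int = 0, dtype=np.float32,
                fused: bool = True) -> nn.SequenceModel:
    """Assemble the layer graph for one architecture variant.

    ``input_shape`` is (window_len, height, width, channels).  Raises
    ValueError when the pooling stack would not divide the image evenly.
    The single conv block of v1 runs as one fused conv+ReLU+pool kernel by
    default (identical mathematics, no intermediate feature maps);
    ``fused=False`` builds the equivalent generic layer stack, which also
    supports float64 for gradient checking.
    """
    t, h, w, c = input_shape
    rng = np.random.default_rng(seed)
    filters = spec.conv_filters()
    frame_layers: list[nn.Layer] = []
    c_in = c
    if len(filters) == 1 and fused and dtype == np.float32:
        if h % 2 or w % 2:
            raise ValueError(f"image {h}x{w} not divisible by the pool")
        frame_layers.append(nn.FusedConvReluPool(c_in, filters[0], rng))
        c_in = filters[0]
        h, w = h // 2, w // 2
    else:
        for i, n_f in enumerate(filters):
            frame_layers.append(nn.Conv3x3Same(c_in, n_f, rng, dtype))
            frame_layers.append(nn.ReLU())
            c_in = n_f
            pool_here = (len(filters) == 1) or (i % 2 == 1)
            if pool_here:
                if h % 2 or w % 2:
                    raise ValueError(
                        f"image {h}x{w} not divisible by the pooling stack")
                frame_layers.append(nn.MaxPool2x2())
                h, w = h // 2, w // 2
    feat = h * w * c_in
    lstm = nn.LSTM(feat, spec.lstm_units, rng, dtype)
    head: list[nn.Layer] = [
        nn.Dense(spec.lstm_units, spec.dense_units, rng, dtype),
        nn.ReLU(),
        nn.Dense(spec.dense_units, n_classes, rng, dtype),
    ]
    return nn.SequenceModel(frame_layers, lstm, head)


def _frame_shape_after(model: nn.SequenceModel,
                       input_shape: tuple[int, ...]) -> tuple[int, ...]:
    return input_shape[1:]


def train(model: nn.SequenceModel, x: np.ndarray, y: np.ndarray,
          cfg: TrainConfig,
          spec: ArchitectureSpec | None = None) -> Checkpoint:
    """Minibatch Adam training under categorical cross-entropy.

    ``x``: (n, T, H, W) or (n, T, H, W, 1), any real dtype (converted to
    float32 per batch); ``y``: int class indices.  Deterministic given
    ``cfg.seed``.  Classes absent from ``y`` trigger a warning in the log.
    """
    if x.ndim == 4:
        x = x[..., None]
    n = len(x)
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    present = np.unique(y)
    n_classes = model.head_layers[-1].params["b"].shape[0]
    history: list[dict] = []
    missing = sorted(set(range(n_classes)) - set(present.tolist()))
    if missing:
        import warnings
        warnings.warn(f"classes absent from the training set: {missing}")
    opt = nn.Adam(model, lr=cfg.learning_rate)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        n_correct = 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb = np.ascontiguousarray(x[idx], dtype=np.float32)
            yb = y[idx]
            logits = model.forward(xb)
            loss, dlogits = nn.cross_entropy(logits, yb)
            model.backward(dlogits.astype(np.float32))
            opt.step()
            total_loss += loss * len(idx)
            n_correct += int((logits.argmax(axis=1) == yb).sum())
        history.append({"epoch": epoch + 1,
                        "loss": total_loss / n,
                        "accuracy": n_correct / n,
                        "batch_size": cfg.batch_size,
                        "learning_rate": cfg.learning_rate})
    return Checkpoint(spec=spec or ArchitectureSpec(),
                      input_shape=tuple(x.shape[1:]),
                      n_classes=n_classes, weights=model.get_weights(),
                      history=history, train_config=cfg)


def predict(model_or_ckpt, x: np.ndarray,
            batch_size: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (lowest index wins ties)."""
    model = (model_or_ckpt.model()
             if isinstance(model_or_ckpt, Checkpoint) else model_or_ckpt)
    if x.ndim == 4:
        x = x[..., None]
    expect = model.frame_layers[0].c_in
    if x.shape[-1] != expect:
        raise ValueError(f"expected {expect} input channels, "
                         f"got {x.shape[-1]}")
    probs = model.predict_proba(np.asarray(x, dtype=np.float32), batch_size)
    return probs, probs.argmax(axis=1)


def samples_to_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    """Stack LabeledSamples into (x uint8, y int) arrays."""
    x = np.stack([s.frames for s in samples]).astype(np.uint8)
    y = np.array([s.label for s in samples], dtype=np.int64)
    return x, y
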