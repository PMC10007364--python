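"""Minimal sequence-classification core: time-distributed convolutions, an
LSTM over per-frame features, dense heads, softmax cross-entropy and Adam.

Implemented directly on NumPy GEMMs (im2col convolutions, batched LSTM gate
pre-activations), in float32 by default; float64 is available for numerical
gradient checking.  Everything is deterministic given the seed handed to
the initializer and the training loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: float arrays in ``params`` mirrored by ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv3x3Same(Layer):
    """3x3 convolution, stride 1, zero ('same') padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = _glorot(rng, (9 * c_in, c_out),
                                   9 * c_in, c_out, dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = sliding_window_view(xp, (3, 3), axis=(1, 2))
        # -> (b, h, w, c, 3, 3); put the window last, channels inside
        cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * w, 9 * c)
        self._cols, self._shape = cols, (b, h, w, c)
        y = cols @ self.params["W"] + self.params["b"]
        return y.reshape(b, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        dyf = dy.reshape(b * h * w, self.c_out)
        self.grads["W"] = self._cols.T @ dyf
        self.grads["b"] = dyf.sum(axis=0)
        dcols = (dyf @ self.params["W"].T).reshape(b, h, w, 3, 3, c)
        dxp = np.zeros((b, h + 2, w + 2, c), dtype=dy.dtype)
        for ky in range(3):
            for kx in range(3):
                dxp[:, ky:ky + h, kx:kx + w, :] += dcols[:, :, :, ky, kx, :]
        self._cols = None
        return dxp[:, 1:h + 1, 1:w + 1, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even, got {h}x{w}")
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c) \
              .transpose(0, 1, 3, 5, 2, 4).reshape(-1, 4)
        self._arg = xr.argmax(axis=1)
        self._shape = (b, h, w, c)
        y = xr[np.arange(xr.shape[0]), self._arg]
        return y.reshape(b, h // 2, w // 2, c)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        flat = np.zeros((b * (h // 2) * (w // 2) * c, 4), dtype=dy.dtype)
        flat[np.arange(flat.shape[0]), self._arg] = dy.ravel()
        return flat.reshape(b, h // 2, w // 2, c, 2, 2) \
                   .transpose(0, 1, 4, 2, 5, 3).reshape(b, h, w, c)


@njit(cache=True, fastmath=True)
def _fused_crp_fwd(xp, W, b):  # pragma: no cover - numba
    """conv3x3(same) + bias + ReLU + 2x2 maxpool in one pass.

    xp: (B, H+2, W+2, C) zero-padded input; W: (9*C, F); b: (F,).
    Returns pooled output (B, H/2, W/2, F) and the uint8 argmax position
    (0..3, row-major within each 2x2 window) of the pre-ReLU maximum.
    """
    B, Hp, Wp, C = xp.shape
    H, Wd = Hp - 2, Wp - 2
    F = W.shape[1]
    out = np.zeros((B, H // 2, Wd // 2, F), dtype=np.float32)
    arg = np.zeros((B, H // 2, Wd // 2, F), dtype=np.uint8)
    v = np.empty((4, F), dtype=np.float32)
    for bi in range(B):
        for oi in range(H // 2):
            for oj in range(Wd // 2):
                for p in range(4):
                    for f in range(F):
                        v[p, f] = b[f]
                for p in range(4):
                    di, dj = p // 2, p % 2
                    i0 = oi * 2 + di
                    j0 = oj * 2 + dj
                    for ky in range(3):
                        for kx in range(3):
                            for c in range(C):
                                xv = xp[bi, i0 + ky, j0 + kx, c]
                                if xv != 0.0:
                                    k = (ky * 3 + kx) * C + c
                                    for f in range(F):
                                        v[p, f] += xv * W[k, f]
                for f in range(F):
                    best = v[0, f]
                    bp = 0
                    for p in range(1, 4):
                        if v[p, f] > best:
                            best = v[p, f]
                            bp = p
                    arg[bi, oi, oj, f] = bp
                    out[bi, oi, oj, f] = best if best > 0.0 else 0.0
    return out, arg


@njit(cache=True, fastmath=True)
def _fused_crp_bwd(xp, out, arg, dpool, C, F):  # pragma: no cover - numba
    """Gradients of the fused layer w.r.t. W and b (input gradient not
    needed: the layer sits at the network input)."""
    B, Ho, Wo, _ = out.shape
    dW = np.zeros((9 * C, F), dtype=np.float32)
    db = np.zeros(F, dtype=np.float32)
    win = np.empty((4, 4, C), dtype=np.float32)
    for bi in range(B):
        for oi in range(Ho):
            for oj in range(Wo):
                # cache the 4x4 input window shared by the 2x2 pool cell
                any_nonzero = False
                for wy in range(4):
                    for wx in range(4):
                        for c in range(C):
                            v = xp[bi, oi * 2 + wy, oj * 2 + wx, c]
                            win[wy, wx, c] = v
                            if v != 0.0:
                                any_nonzero = True
                for f in range(F):
                    if out[bi, oi, oj, f] > 0.0:
                        g = dpool[bi, oi, oj, f]
                        if g != 0.0:
                            db[f] += g
                            if any_nonzero:
                                p = arg[bi, oi, oj, f]
                                di = p // 2
                                dj = p % 2
                                for ky in range(3):
                                    for kx in range(3):
                                        for c in range(C):
                                            xv = win[di + ky, dj + kx, c]
                                            if xv != 0.0:
                                                dW[(ky * 3 + kx) * C + c,
                                                   f] += xv * g
    return dW, db


class FusedConvReluPool(Layer):
    """3x3 same conv + ReLU + 2x2 maxpool fused into numba kernels.

    Mathematically identical to ``Conv3x3Same -> ReLU -> MaxPool2x2`` (ReLU
    and max commute), but avoids materializing the pre-pool feature maps,
    which dominate the cost of the grid-variant network.  float32 only.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator
                 ) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = _glorot(rng, (9 * c_in, c_out),
                                   9 * c_in, c_out, np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(np.ascontiguousarray(x, dtype=np.float32),
                    ((0, 0), (1, 1), (1, 1), (0, 0)))
        out, arg = _fused_crp_fwd(xp, self.params["W"], self.params["b"])
        self._xp, self._out, self._arg = xp, out, arg
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        dW, db = _fused_crp_bwd(self._xp, self._out, self._arg,
                                np.ascontiguousarray(dy, dtype=np.float32),
                                self.c_in, self.c_out)
        self.grads["W"] = dW
        self.grads["b"] = db
        self._xp = self._out = self._arg = None
        return None


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.params["W"] = _glorot(rng, (n_in, n_out), n_in, n_out, dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Single LSTM layer returning the final hidden state.

    Gate order (i, f, g, o); forget-gate bias initialized to 1.  The
    input-to-gate product for all timesteps is computed as one GEMM, which
    dominates the cost for wide per-frame feature vectors.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.n_in, self.n_hidden = n_in, n_hidden
        h4 = 4 * n_hidden
        self.params["Wx"] = _glorot(rng, (n_in, h4), n_in, h4, dtype)
        self.params["Wh"] = _glorot(rng, (n_hidden, h4), n_hidden, h4, dtype)
        b = np.zeros(h4, dtype=dtype)
        b[n_hidden:2 * n_hidden] = 1.0
        self.params["b"] = b

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, d = x.shape
        hdim = self.n_hidden
        xg = x.reshape(b * t, d) @ self.params["Wx"] + self.params["b"]
        xg = xg.reshape(b, t, 4 * hdim)
        h = np.zeros((b, hdim), dtype=x.dtype)
        c = np.zeros((b, hdim), dtype=x.dtype)
        cache = []
        for k in range(t):
            g = xg[:, k] + h @ self.params["Wh"]
            i = _sigmoid(g[:, :hdim])
            f = _sigmoid(g[:, hdim:2 * hdim])
            gg = np.tanh(g[:, 2 * hdim:3 * hdim])
            o = _sigmoid(g[:, 3 * hdim:])
            c_new = f * c + i * gg
            tc = np.tanh(c_new)
            cache.append((h, c, i, f, gg, o, tc))
            h, c = o * tc, c_new
        self._x, self._cache, self._bt = x, cache, (b, t)
        return h

    def backward(self, dh_last: np.ndarray) -> np.ndarray:
        b, t = self._bt
        hdim = self.n_hidden
        Wh = self.params["Wh"]
        dgates = np.zeros((b, t, 4 * hdim), dtype=dh_last.dtype)
        dWh = np.zeros_like(Wh)
        dh = dh_last
        dc = np.zeros_like(dh_last)
        for k in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, gg, o, tc = self._cache[k]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            dg = dgates[:, k]
            dg[:, :hdim] = (dc * gg) * i * (1 - i)
            dg[:, hdim:2 * hdim] = (dc * c_prev) * f * (1 - f)
            dg[:, 2 * hdim:3 * hdim] = (dc * i) * (1 - gg * gg)
            dg[:, 3 * hdim:] = do * o * (1 - o)
            dWh += h_prev.T @ dg
            dh = dg @ Wh.T
            dc = dc * f
        dgf = dgates.reshape(b * t, 4 * hdim)
        xf = self._x.reshape(b * t, self.n_in)
        self.grads["Wx"] = xf.T @ dgf
        self.grads["Wh"] = dWh
        self.grads["b"] = dgf.sum(axis=0)
        dx = (dgf @ self.params["Wx"].T).reshape(b, t, self.n_in)
        self._x = self._cache = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class SequenceModel:
    """Per-frame feature layers -> LSTM over time -> dense head.

    Input shape (batch, time, height, width, channels); the per-frame stack
    is applied with time folded into the batch axis (time-distributed).
    """

    def __init__(self, frame_layers: list[Layer], lstm: LSTM,
                 head_layers: list[Layer]) -> None:
        self.frame_layers = frame_layers
        self.lstm = lstm
        self.head_layers = head_layers

    @property
    def layers(self) -> list[Layer]:
        return [*self.frame_layers, self.lstm, *self.head_layers]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t = x.shape[:2]
        z = x.reshape(b * t, *x.shape[2:])
        for layer in self.frame_layers:
            z = layer.forward(z)
        self._frame_out_shape = z.shape[1:]
        z = z.reshape(b, t, -1)
        z = self.lstm.forward(z)
        for layer in self.head_layers:
            z = layer.forward(z)
        return z

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.head_layers):
            d = layer.backward(d)
        d = self.lstm.backward(d)
        b, t = d.shape[:2]
        d = d.reshape(b * t, *self._frame_out_shape)
        for layer in reversed(self.frame_layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32
                      ) -> np.ndarray:
        out = []
        for lo in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[lo:lo + batch_size])))
        return np.concatenate(out) if out else np.empty((0, 0))

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"{i}.{k}": v for i, layer in enumerate(self.layers)
                for k, v in layer.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k] = weights[f"{i}.{k}"].copy()


@njit(cache=True, fastmath=True)
def _adam_update(p, g, m, v, lr, b1, b2, eps, b1c, b2c
                 ):  # pragma: no cover - numba
    for i in range(p.size):
        gi = g[i]
        m[i] = b1 * m[i] + (1.0 - b1) * gi
        v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
        p[i] -= lr * (m[i] / b1c) / (math.sqrt(v[i] / b2c) + eps)


class Adam:
    def __init__(self, model: SequenceModel, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v)
                  for k, v in model.get_weights().items()}
        self.v = {k: np.zeros_like(v)
                  for k, v in model.get_weights().items()}

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for i, layer in enumerate(self.model.layers):
            for k, p in layer.params.items():
                key = f"{i}.{k}"
                if p.dtype == np.float32:
                    _adam_update(p.ravel(), layer.grads[k].ravel(),
                                 self.m[key].ravel(), self.v[key].ravel(),
                                 self.lr, self.beta1, self.beta2, self.eps,
                                 b1c, b2c)
                else:
                    g = layer.grads[k]
                    m = self.m[key]
                    v = self.v[key]
                    m *= self.beta1
                    m += (1 - self.beta1) * g
                    v *= self.beta2
                    v += (1 - self.beta2) * g * g
                    p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
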