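"""Minimal CPU neural-network core used by the pileup and full-alignment callers.

Implements exactly the pieces the callers need — 2-D convolution, residual
blocks, spatial pyramid pooling (SPP), dense layers, multi-head softmax
cross-entropy and Adam — with hand-written backward passes on numpy arrays.
All tensors are ``(batch, channels, height, width)`` float64. Widths are kept
small by the callers so that training runs in minutes on one CPU core.

Determinism: every source of randomness (weight init, batch shuffling) is
driven by a ``numpy.random.Generator`` seeded by the caller, and all ops are
plain numpy, so repeated runs with the same seed produce identical weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "Dense",
    "Flatten",
    "ResBlock",
    "SpatialPyramidPooling",
    "MultiTaskNet",
    "AdamOptimizer",
    "softmax",
    "numeric_gradient_check",
]


# float32 keeps the matmuls fast on CPU; tests that need tighter numeric
# agreement (gradient checking) may set nn.DTYPE = np.float64 before
# building a network.
DTYPE = np.float32


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    """Base class; layers expose params()/grads() as parallel lists."""

    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int,
            ph: int, pw: int) -> Tuple[np.ndarray, Tuple[int, int]]:
    """Return (B*oh*ow, C*kh*kw) patches and the output spatial shape."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    oh = (h + 2 * ph - kh) // sh + 1
    ow = (w + 2 * pw - kw) // sw + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::sh, ::sw, :, :]              # (B,C,oh,ow,kh,kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), (oh, ow)


class Conv2d(Layer):
    """3x3 (or any odd) convolution with 'same' padding and optional stride."""

    def __init__(self, c_in: int, c_out: int, kernel: Tuple[int, int] = (3, 3),
                 stride: Tuple[int, int] = (1, 1), rng: Optional[np.random.Generator] = None):
        kh, kw = kernel
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kh * kw
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, kh, kw)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self.stride = stride
        self.pad = (kh // 2, kw // 2)
        self._cache: Optional[tuple] = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.w.dtype)
        kh, kw = self.kernel
        sh, sw = self.stride
        ph, pw = self.pad
        cols, (oh, ow) = _im2col(x, kh, kw, sh, sw, ph, pw)
        c_out = self.w.shape[0]
        wmat = self.w.reshape(c_out, -1)
        out = cols @ wmat.T                                # (B*oh*ow, c_out)
        out += self.b
        self._cache = (x.shape, cols, oh, ow)
        b = x.shape[0]
        return np.ascontiguousarray(
            out.reshape(b, oh * ow, c_out).transpose(0, 2, 1)
        ).reshape(b, c_out, oh, ow)

    def backward(self, dout: np.ndarray,
                 need_dx: bool = True) -> Optional[np.ndarray]:
        x_shape, cols, oh, ow = self._cache
        b, c, h, w = x_shape
        kh, kw = self.kernel
        sh, sw = self.stride
        ph, pw = self.pad
        c_out = self.w.shape[0]
        dflat = np.ascontiguousarray(
            dout.reshape(b, c_out, oh * ow).transpose(0, 2, 1)
        ).reshape(b * oh * ow, c_out)
        self.dw[...] = (dflat.T @ cols).reshape(self.w.shape)
        self.db[...] = dflat.sum(axis=0)
        if not need_dx:        # first layer: the input gradient is unused
            return None
        dcols = dflat @ self.w.reshape(c_out, -1)          # (B*oh*ow, C*kh*kw)
        dcols = dcols.reshape(b, oh, ow, c, kh, kw)
        dxp = np.zeros((b, c, h + 2 * ph, w + 2 * pw), dtype=self.w.dtype)
        # scatter-add each kernel offset back; kh*kw iterations only
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + oh * sh:sh, j:j + ow * sw:sw] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, ph:ph + h, pw:pw + w]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in),
                            size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x):
        self._x = np.ascontiguousarray(x, dtype=self.w.dtype)
        return self._x @ self.w + self.b

    def backward(self, dout):
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w.T


class ResBlock(Layer):
    """Two same-shape convolutions with an identity skip: y = relu(x + F(x))."""

    def __init__(self, channels: int, rng: Optional[np.random.Generator] = None):
        self.conv1 = Conv2d(channels, channels, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, rng=rng)
        self.relu_out = ReLU()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def grads(self):
        return self.conv1.grads() + self.conv2.grads()

    def forward(self, x):
        f = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu_out.forward(x + f)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        df = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        return d + df


class SpatialPyramidPooling(Layer):
    """Adaptive pooling at several grid levels, concatenated.

    Each level is an ``(h_bins, w_bins)`` grid (a bare int ``n`` means an
    ``n x n`` grid); each bin is pooled with every mode in ``modes`` ("max",
    "mean"). Output length is ``channels * len(modes) * sum(h*w)`` regardless
    of the spatial extent of the input, which is what lets the caller feed
    tensors with any number of read rows into the same dense head. Levels
    with many position bins but one row bin (e.g. ``(33, 1)``) keep the
    genome-position structure while staying invariant to the read-row count.
    """

    def __init__(self, levels: Sequence = (1, 2, 4),
                 modes: Sequence[str] = ("max", "mean")):
        self.levels = tuple((lv, lv) if isinstance(lv, int) else tuple(lv)
                            for lv in levels)
        self.modes = tuple(modes)

    @property
    def bins_per_channel(self) -> int:
        return len(self.modes) * sum(h * w for h, w in self.levels)

    @staticmethod
    def _edges(n: int, bins: int) -> np.ndarray:
        return np.floor(np.linspace(0, n, bins + 1)).astype(int)

    def forward(self, x):
        b, c, h, w = x.shape
        self._xshape = x.shape
        outs = []
        self._cache = []
        for hb, wb in self.levels:
            if hb == h:
                # fast path: one bin per position, rows split into wb chunks
                # pooled with vectorized reductions
                we = self._edges(w, wb)
                chunks = []
                for j in range(wb):
                    w0, w1 = we[j], max(we[j + 1], we[j] + 1)
                    w1 = min(w1, w)
                    sub = x[:, :, :, w0:w1]
                    idx = sub.argmax(axis=3)
                    cmax = np.take_along_axis(
                        sub, idx[:, :, :, None], axis=3)[..., 0]
                    chunks.append((w0, w1, cmax, sub.mean(axis=3), idx))
                for i in range(h):
                    for (w0, w1, cmax, cmean, idx) in chunks:
                        for mode in self.modes:
                            if mode == "max":
                                outs.append(cmax[:, :, i])
                                self._cache.append((i, i + 1, w0, w1, "max",
                                                    idx[:, :, i]))
                            else:
                                outs.append(cmean[:, :, i])
                                self._cache.append((i, i + 1, w0, w1,
                                                    "mean", None))
                continue
            he = self._edges(h, hb)
            we = self._edges(w, wb)
            for i in range(hb):
                for j in range(wb):
                    h0, h1 = he[i], max(he[i + 1], he[i] + 1)
                    w0, w1 = we[j], max(we[j + 1], we[j] + 1)
                    h1, w1 = min(h1, h), min(w1, w)
                    patch = x[:, :, h0:h1, w0:w1].reshape(b, c, -1)
                    for mode in self.modes:
                        if mode == "max":
                            idx = patch.argmax(axis=2)
                            outs.append(np.take_along_axis(
                                patch, idx[:, :, None], axis=2)[:, :, 0])
                            self._cache.append((h0, h1, w0, w1, "max", idx))
                        else:
                            outs.append(patch.mean(axis=2))
                            self._cache.append((h0, h1, w0, w1, "mean", None))
        return np.concatenate(outs, axis=1)

    def backward(self, dout):
        b, c, h, w = self._xshape
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        col = 0
        for (h0, h1, w0, w1, mode, idx) in self._cache:
            d = dout[:, col:col + c]
            col += c
            n_el = (h1 - h0) * (w1 - w0)
            if mode == "max":
                dpatch = np.zeros((b, c, n_el), dtype=dout.dtype)
                np.put_along_axis(dpatch, idx[:, :, None], d[:, :, None], axis=2)
                dx[:, :, h0:h1, w0:w1] += dpatch.reshape(b, c, h1 - h0, w1 - w0)
            else:
                dx[:, :, h0:h1, w0:w1] += (d / n_el)[:, :, None, None]
        return dx


@dataclass
class AdamOptimizer:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: list = field(default_factory=list)
    _v: list = field(default_factory=list)
    _t: int = 0

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        if not self._m:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1t = 1 - self.beta1 ** self._t
        b2t = 1 - self.beta2 ** self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class MultiTaskNet:
    """A trunk of layers feeding shared features into several softmax heads.

    ``heads`` maps a task name to its number of classes; each head is a single
    dense layer over the shared hidden representation. The training loss is
    the unweighted sum of the per-head cross-entropies.
    """

    def __init__(self, trunk: List[Layer], hidden_in: int, hidden: int,
                 heads: Dict[str, int], rng: np.random.Generator):
        self.trunk = trunk
        self.shared = [Dense(hidden_in, hidden, rng=rng), ReLU()]
        self.head_order = list(heads.keys())
        self.heads = {name: Dense(hidden, n, rng=rng) for name, n in heads.items()}

    # -- parameter plumbing -------------------------------------------------
    def _all_layers(self) -> List[Layer]:
        return self.trunk + self.shared + [self.heads[n] for n in self.head_order]

    def params(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for l in self._all_layers():
            out.extend(l.params())
        return out

    def grads(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for l in self._all_layers():
            out.extend(l.grads())
        return out

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> Dict[str, np.ndarray]:
        h = x
        for l in self.trunk:
            h = l.forward(h)
        for l in self.shared:
            h = l.forward(h)
        return {name: self.heads[name].forward(h) for name in self.head_order}

    def predict_proba(self, x: np.ndarray) -> Dict[str, np.ndarray]:
        return {k: softmax(v) for k, v in self.forward(x).items()}

    def loss_and_backward(self, x: np.ndarray,
                          labels: Dict[str, np.ndarray]) -> float:
        logits = self.forward(x)
        b = x.shape[0]
        dshared = None
        total = 0.0
        for name in self.head_order:
            z = logits[name]
            p = softmax(z)
            y = labels[name]
            total += -np.log(np.maximum(p[np.arange(b), y], 1e-12)).sum() / b
            dz = p.copy()
            dz[np.arange(b), y] -= 1.0
            dz /= b
            dh = self.heads[name].backward(dz)
            dshared = dh if dshared is None else dshared + dh
        d = dshared
        for l in reversed(self.shared):
            d = l.backward(d)
        first = self.trunk[0]
        for l in reversed(self.trunk):
            if l is first and isinstance(l, Conv2d):
                l.backward(d, need_dx=False)
            else:
                d = l.backward(d)
        return float(total)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str, metadata: Optional[dict] = None) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params())}
        arrays["__meta__"] = np.frombuffer(
            json.dumps(metadata or {}).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    def load_weights(self, path: str) -> dict:
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as z:
            meta = json.loads(bytes(z["__meta__"]).decode()) if "__meta__" in z else {}
            for i, p in enumerate(self.params()):
                p[...] = z[f"p{i}"]
        return meta


def load_checkpoint_metadata(path: str) -> dict:
    """Read only the metadata block embedded in a checkpoint file."""
    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as z:
        return json.loads(bytes(z["__meta__"]).decode()) if "__meta__" in z else {}


def fit(net: MultiTaskNet, x: np.ndarray, labels: Dict[str, np.ndarray],
        epochs: int, seed: int, batch_size: int = 32, lr: float = 1e-3,
        val_fraction: float = 0.10, input_scale: float = 1.0) -> List[dict]:
    """Train with Adam on summed cross-entropies; keep the best-validation
    weights.

    A ``val_fraction`` share of the examples is held out at random (seeded)
    for validation; after every epoch the validation loss is evaluated and
    the weights with the lowest validation loss are restored at the end.
    With ``val_fraction=0`` the final weights are kept. Returns the per-epoch
    history (train loss, validation loss, validation accuracy per head).
    """
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if train_idx.size == 0:
        raise ValueError("no training examples left after validation split")
    opt = AdamOptimizer(lr=lr)
    history: List[dict] = []
    best_val = np.inf
    best_weights: Optional[List[np.ndarray]] = None

    def to_float(sel: np.ndarray) -> np.ndarray:
        xb = np.asarray(x[sel], dtype=DTYPE)
        return xb / DTYPE(input_scale) if input_scale != 1.0 else xb

    for epoch in range(epochs):
        # step decay: drop the learning rate for the final third of training
        opt.lr = lr * (0.3 if epoch >= (2 * epochs) // 3 else 1.0)
        order = rng.permutation(train_idx)
        total = 0.0
        for i in range(0, order.size, batch_size):
            sel = order[i:i + batch_size]
            batch_labels = {k: v[sel] for k, v in labels.items()}
            total += net.loss_and_backward(to_float(sel), batch_labels) * sel.size
            opt.step(net.params(), net.grads())
        rec = {"epoch": epoch, "train_loss": total / order.size,
               "n_train": int(order.size), "n_val": int(val_idx.size)}
        if val_idx.size:
            xv = to_float(val_idx)
            rec["val_loss"] = _loss_only(
                net, xv, {k: v[val_idx] for k, v in labels.items()})
            probs = net.predict_proba(xv)
            for k, p in probs.items():
                rec[f"val_acc_{k}"] = float(
                    (p.argmax(axis=1) == labels[k][val_idx]).mean())
            if rec["val_loss"] < best_val:
                best_val = rec["val_loss"]
                best_weights = [p.copy() for p in net.params()]
        history.append(rec)
    if best_weights is not None:
        for p, w in zip(net.params(), best_weights):
            p[...] = w
    return history


def numeric_gradient_check(net: MultiTaskNet, x: np.ndarray,
                           labels: Dict[str, np.ndarray],
                           n_checks: int = 20, eps: float = 1e-5,
                           seed: int = 0) -> float:
    """Max relative error between analytic and central-difference gradients."""
    net.loss_and_backward(x, labels)
    analytic = [g.copy() for g in net.grads()]
    rng = np.random.default_rng(seed)
    worst = 0.0
    params = net.params()
    for _ in range(n_checks):
        pi = rng.integers(len(params))
        p = params[pi]
        flat = rng.integers(p.size)
        idx = np.unravel_index(flat, p.shape)
        orig = p[idx]
        p[idx] = orig + eps
        lp = _loss_only(net, x, labels)
        p[idx] = orig - eps
        lm = _loss_only(net, x, labels)
        p[idx] = orig
        num = (lp - lm) / (2 * eps)
        ana = analytic[pi][idx]
        denom = max(abs(num), abs(ana), 1e-8)
        worst = max(worst, abs(num - ana) / denom)
    return worst


def _loss_only(net: MultiTaskNet, x: np.ndarray, labels: Dict[str, np.ndarray]) -> float:
    logits = net.forward(x)
    b = x.shape[0]
    total = 0.0
    for name, z in logits.items():
        p = softmax(z)
        total += -np.log(np.maximum(p[np.arange(b), labels[name]], 1e-12)).sum() / b
    return float(total)
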