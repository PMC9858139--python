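"""Lightweight CNN: declarative architecture, exact parameter accounting,
forward-math primitives, and a 5-fold training/evaluation harness.

The network is built from four blocks of "ConvNet" cells (convolution ->
batch norm -> softplus), all with valid padding:

    Block 1: 5x5/32 stride 2
    Block 2: 3x3/48 stride 2, 3x3/48, 1x1/48, add, 2x2 avg-pool stride 2
    Block 3: 3x3/64,          3x3/64, 1x1/64, add, 2x2 avg-pool stride 2
    Block 4: 3x3/128,         3x3/128, 1x1/128, add, 2x2 avg-pool stride 2

followed by global average pooling, a 2-unit dense layer and softmax.  The
add junction sums the outputs of the 2nd and 3rd ConvNets of each block (the
only shape-compatible pair).  At the default 224x224x3 input this comes to
349,458 parameters (347,954 trainable + 1,504 batch-norm running statistics).

The training engine below is a self-contained numpy implementation —
im2col convolutions with analytic backprop, batch-norm train/inference
modes, and the seven first-order optimizers the harness exposes (SGDM,
Adam, AdaMax, Adagrad, Adadelta, RMSProp, Nadam).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .augment import AugmentConfig, augment_dataset
from .core_io import LabeledDataset, labels_to_int, to_gray_stack
from .metrics import MetricsReport, classification_metrics, confusion, summarize_folds

logger = logging.getLogger(__name__)


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


# ---------------------------------------------------------------------------
# Declarative architecture and exact accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    kind: str                 # conv | batchnorm | softplus | avgpool | add | gap | dense | softmax
    kernel: int = 0
    stride: int = 1
    filters: int = 0          # conv filters or dense units
    skip_from: int = -1       # add: index of the layer whose output is summed in
    block: int = 0

    def __post_init__(self) -> None:
        if self.kind in ("conv", "avgpool") and self.kernel < 1:
            raise ValueError(f"{self.kind} needs kernel >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.kind == "conv" and self.filters < 1:
            raise ValueError("conv needs filters >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    input_shape: tuple[int, int, int] = (224, 224, 3)
    layers: tuple[LayerSpec, ...] = ()
    num_classes: int = 2


@dataclass(frozen=True)
class ParamBreakdown:
    per_layer: tuple[tuple[str, int, int], ...]   # (label, trainable, nontrainable)
    trainable_total: int
    nontrainable_total: int

    @property
    def total(self) -> int:
        return self.trainable_total + self.nontrainable_total


def conv_out_shape(in_shape: tuple[int, int, int], kernel: int, stride: int,
                   filters: int) -> tuple[int, int, int]:
    """Valid-padding output shape: ``floor((in - kernel)/stride) + 1`` per axis."""
    h, w, _ = in_shape
    if kernel > min(h, w):
        raise ValueError(f"kernel {kernel} exceeds spatial size {(h, w)}")
    return ((h - kernel) // stride + 1, (w - kernel) // stride + 1, filters)


def conv_param_count(kernel: int, c_in: int, c_out: int) -> int:
    """``kernel^2 * c_in * c_out`` weights plus one bias per filter."""
    return kernel * kernel * c_in * c_out + c_out


def bn_param_count(channels: int) -> tuple[int, int]:
    """(trainable, nontrainable): scale+shift vs. running mean+variance."""
    return 2 * channels, 2 * channels


def build_architecture(input_size: int = 224, num_classes: int = 2,
                       use_add: bool = True) -> ArchitectureSpec:
    """The default lightweight architecture (four ConvNet blocks)."""
    layers: list[LayerSpec] = []

    def convnet(kernel: int, filters: int, stride: int, block: int) -> int:
        layers.append(LayerSpec("conv", kernel=kernel, stride=stride,
                                filters=filters, block=block))
        layers.append(LayerSpec("batchnorm", block=block))
        layers.append(LayerSpec("softplus", block=block))
        return len(layers) - 1          # index of the cell's output (softplus)

    convnet(5, 32, 2, block=1)
    for block, (filters, first_stride) in enumerate(
            [(48, 2), (64, 1), (128, 1)], start=2):
        convnet(3, filters, first_stride, block)
        mid = convnet(3, filters, 1, block)
        convnet(1, filters, 1, block)
        if use_add:
            layers.append(LayerSpec("add", skip_from=mid, block=block))
        layers.append(LayerSpec("avgpool", kernel=2, stride=2, block=block))
    layers.append(LayerSpec("gap"))
    layers.append(LayerSpec("dense", filters=num_classes))
    layers.append(LayerSpec("softmax"))
    return ArchitectureSpec(input_shape=(input_size, input_size, 3),
                            layers=tuple(layers), num_classes=num_classes)


def shape_trace(spec: ArchitectureSpec) -> list[tuple[str, tuple]]:
    """Per-layer activation shapes, starting with the input row.

    Conv/pool shapes obey the valid/floor formula; add operands must be
    shape-equal; GAP collapses to (channels,).
    """
    shapes: list[tuple] = []
    trace: list[tuple[str, tuple]] = [("input", spec.input_shape)]
    cur: tuple = spec.input_shape
    for i, ly in enumerate(spec.layers):
        if ly.kind == "conv":
            cur = conv_out_shape(cur, ly.kernel, ly.stride, ly.filters)
        elif ly.kind == "avgpool":
            h, w, c = cur
            cur = ((h - ly.kernel) // ly.stride + 1, (w - ly.kernel) // ly.stride + 1, c)
        elif ly.kind == "add":
            other = shapes[ly.skip_from]
            if other != cur:
                raise ValueError(f"add operands differ: {other} vs {cur}")
        elif ly.kind == "gap":
            cur = (cur[2],)
        elif ly.kind == "dense":
            cur = (ly.filters,)
        # batchnorm / softplus / softmax preserve shape
        shapes.append(cur)
        trace.append((ly.kind, cur))
    return trace


def count_params(spec: ArchitectureSpec) -> ParamBreakdown:
    """Exact parameter accounting (pool/GAP/softplus/add/softmax are free)."""
    per_layer: list[tuple[str, int, int]] = []
    cur = spec.input_shape
    shapes: list[tuple] = []
    for ly in spec.layers:
        if ly.kind == "conv":
            n = conv_param_count(ly.kernel, cur[2], ly.filters)
            cur = conv_out_shape(cur, ly.kernel, ly.stride, ly.filters)
            per_layer.append((f"conv{ly.kernel}x{ly.kernel}/{ly.filters}", n, 0))
        elif ly.kind == "batchnorm":
            tr, nt = bn_param_count(cur[2])
            per_layer.append((f"batchnorm/{cur[2]}", tr, nt))
        elif ly.kind == "avgpool":
            h, w, c = cur
            cur = ((h - ly.kernel) // ly.stride + 1, (w - ly.kernel) // ly.stride + 1, c)
            per_layer.append(("avgpool", 0, 0))
        elif ly.kind == "gap":
            cur = (cur[2],)
            per_layer.append(("gap", 0, 0))
        elif ly.kind == "dense":
            n = cur[0] * ly.filters + ly.filters
            cur = (ly.filters,)
            per_layer.append((f"dense/{ly.filters}", n, 0))
        else:
            per_layer.append((ly.kind, 0, 0))
        shapes.append(cur)
    return ParamBreakdown(
        per_layer=tuple(per_layer),
        trainable_total=sum(t for _, t, _ in per_layer),
        nontrainable_total=sum(n for _, _, n in per_layer),
    )


# ---------------------------------------------------------------------------
# Forward-math primitives (also used as oracles for the engine)
# ---------------------------------------------------------------------------

def softplus(x):
    """``log(1 + e^x)``, overflow-safe for large |x|."""
    return np.logaddexp(0.0, np.asarray(x, dtype=np.float64))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Exponentiate-and-normalize with max subtraction for stability."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def batchnorm_forward(batch: np.ndarray, gamma: float = 1.0, xi: float = 0.0,
                      eps: float = 1e-5) -> np.ndarray:
    """Normalize a mini-batch with its own (population) statistics:

        mu = mean(F), sigma^2 = var(F), F_hat = (F - mu)/sqrt(sigma^2 + eps),
        bn(F) = gamma * F_hat + xi
    """
    b = np.asarray(batch, dtype=np.float64)
    mu = b.mean(axis=0)
    var = b.var(axis=0)
    return gamma * (b - mu) / np.sqrt(var + eps) + xi


# ---------------------------------------------------------------------------
# numpy training engine
# ---------------------------------------------------------------------------

class _Conv:
    def __init__(self, spec: LayerSpec, c_in: int, rng: np.random.Generator):
        k, f = spec.kernel, spec.filters
        fan_in = k * k * c_in
        self.k, self.s = k, spec.stride
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(k * k * c_in, f)).astype(np.float32)
        self.b = np.zeros(f, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        k, s = self.k, self.s
        B, H, W, C = x.shape
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]                              # (B,Ho,Wo,C,k,k)
        Ho, Wo = win.shape[1], win.shape[2]
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)
                                    ).reshape(B, Ho, Wo, k * k * C)
        out = cols.reshape(-1, k * k * C) @ self.W + self.b
        if training:
            self._cache = (cols, x.shape)
        return out.reshape(B, Ho, Wo, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        B, Ho, Wo, _ = dout.shape
        k, s = self.k, self.s
        d2 = dout.reshape(-1, dout.shape[-1])
        self.grads[0][...] = cols.reshape(-1, cols.shape[-1]).T @ d2
        self.grads[1][...] = d2.sum(axis=0)
        dcols = (d2 @ self.W.T).reshape(B, Ho, Wo, k, k, xshape[3])
        dx = np.zeros(xshape, dtype=np.float32)
        for a in range(k):
            for b in range(k):
                dx[:, a:a + s * Ho:s, b:b + s * Wo:s, :] += dcols[:, :, :, a, b, :]
        self._cache = None
        return dx


class _BatchNorm:
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.eps, self.momentum = eps, momentum
        self.gamma = np.ones(channels, dtype=np.float32)
        self.xi = np.zeros(channels, dtype=np.float32)
        # exponential moving averages, stored raw and debiased at inference
        # (by 1 - momentum^t) so early-training evaluation is already sane;
        # overridden by exact population moments after finalize_bn()
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.zeros(channels, dtype=np.float32)
        self.n_updates = 0
        self.finalized = False
        self._collect: list | None = None
        self.params = [self.gamma, self.xi]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.xi)]
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self._collect is not None:
                n = int(np.prod([x.shape[a] for a in axes]))
                self._collect.append((mu.copy(), var.copy(), n))
            else:
                m = self.momentum
                self.run_mean[...] = m * self.run_mean + (1 - m) * mu
                self.run_var[...] = m * self.run_var + (1 - m) * var
                self.n_updates += 1
        elif self.finalized:
            mu, var = self.run_mean, self.run_var
        elif self.n_updates == 0:
            mu = np.zeros_like(self.run_mean)
            var = np.ones_like(self.run_var)
        else:
            corr = 1.0 - self.momentum**self.n_updates
            mu, var = self.run_mean / corr, self.run_var / corr
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * istd
        if training:
            self._cache = (xhat, istd, x.shape)
        return self.gamma * xhat + self.xi

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, istd, shape = self._cache
        axes = tuple(range(dout.ndim - 1))
        n = float(np.prod([shape[a] for a in axes]))
        dg = (dout * xhat).sum(axis=axes)
        db = dout.sum(axis=axes)
        self.grads[0][...] = dg
        self.grads[1][...] = db
        dx = (self.gamma * istd / n) * (n * dout - db - xhat * dg)
        self._cache = None
        return dx.astype(np.float32)


class _Softplus:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        # float32-stable softplus
        return np.logaddexp(0.0, x).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * _sigmoid(self._x.astype(np.float64)).astype(np.float32)
        self._x = None
        return dx


class _AvgPool2:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, H, W, C = x.shape
        Ho, Wo = (H - 2) // 2 + 1, (W - 2) // 2 + 1
        v = x[:, :2 * Ho, :2 * Wo].reshape(B, Ho, 2, Wo, 2, C)
        if training:
            self._shape = x.shape
        return v.mean(axis=(2, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, Ho, Wo, C = dout.shape
        dx = np.zeros(self._shape, dtype=np.float32)
        d = np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2) * 0.25
        dx[:, :2 * Ho, :2 * Wo] = d
        return dx


class _GAP:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        _, H, W, _ = self._shape
        return (np.broadcast_to(dout[:, None, None, :], self._shape)
                / (H * W)).astype(np.float32)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in),
                            size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class _Add:
    """Residual junction; gradient routing is handled by the network."""
    params: list = []
    grads: list = []


class Network:
    """A concrete numpy network instantiated from an :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        shapes = [s for _, s in shape_trace(spec)][1:]   # per-layer output shapes
        cur_c = spec.input_shape[2]
        self.layers: list = []
        for i, ly in enumerate(spec.layers):
            if ly.kind == "conv":
                self.layers.append(_Conv(ly, cur_c, rng))
                cur_c = ly.filters
            elif ly.kind == "batchnorm":
                self.layers.append(_BatchNorm(cur_c))
            elif ly.kind == "softplus":
                self.layers.append(_Softplus())
            elif ly.kind == "avgpool":
                self.layers.append(_AvgPool2())
            elif ly.kind == "add":
                self.layers.append(_Add())
            elif ly.kind == "gap":
                self.layers.append(_GAP())
            elif ly.kind == "dense":
                self.layers.append(_Dense(shapes[i - 1][0] if len(shapes[i - 1]) == 1
                                          else shapes[i - 1][-1], ly.filters, rng))
            elif ly.kind == "softmax":
                self.layers.append(None)    # folded into the loss / predict
            else:  # pragma: no cover
                raise ValueError(f"unknown layer kind {ly.kind}")

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [p for l in self.layers if l is not None for p in l.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for l in self.layers if l is not None for g in l.grads]

    def num_params(self) -> tuple[int, int]:
        """(trainable, nontrainable) from the actually allocated arrays."""
        trainable = sum(p.size for p in self.parameters())
        nontrainable = sum(l.run_mean.size + l.run_var.size
                           for l in self.layers if isinstance(l, _BatchNorm))
        return trainable, nontrainable

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a (B, H, W, 3) float32 batch."""
        outs: list[np.ndarray | None] = [None] * len(self.spec.layers)
        cur = x.astype(np.float32)
        for i, (ly, layer) in enumerate(zip(self.spec.layers, self.layers)):
            if ly.kind == "add":
                cur = cur + outs[ly.skip_from]
            elif ly.kind == "softmax":
                pass                         # applied in predict_proba / loss
            else:
                cur = layer.forward(cur, training)
            outs[i] = cur
        self._outs = outs if training else None
        return cur

    def backward(self, dlogits: np.ndarray) -> None:
        pending: dict[int, np.ndarray] = {}
        d = dlogits.astype(np.float32)
        for i in range(len(self.spec.layers) - 1, -1, -1):
            if i in pending:
                d = d + pending.pop(i)
            ly, layer = self.spec.layers[i], self.layers[i]
            if ly.kind == "add":
                pending[ly.skip_from] = d.copy()   # skip path; chain path continues
            elif ly.kind == "softmax":
                continue
            else:
                d = layer.backward(d)
        self._outs = None

    def finalize_bn(self, X: np.ndarray, batch: int = 32) -> None:
        """Replace batch-norm running averages by exact population moments.

        Runs forward passes in training mode (so downstream layers see the
        same normalization as during optimization), collects every layer's
        per-batch moments and combines them into population statistics
        (law of total variance across batches).  Removes the train/inference
        normalization mismatch that an unconverged moving average leaves
        behind after short training runs.
        """
        bns = [l for l in self.layers if isinstance(l, _BatchNorm)]
        for l in bns:
            l._collect = []
        try:
            for lo in range(0, len(X), batch):
                self.forward(X[lo:lo + batch], training=True)
        finally:
            for l in bns:
                stats = l._collect
                l._collect = None
                if not stats:
                    continue
                w = np.array([n for _, _, n in stats], dtype=np.float64)
                w = w / w.sum()
                mus = np.stack([m for m, _, _ in stats])
                vrs = np.stack([v for _, v, _ in stats])
                mu = (w[:, None] * mus).sum(axis=0)
                var = (w[:, None] * (vrs + (mus - mu) ** 2)).sum(axis=0)
                l.run_mean[...] = mu.astype(np.float32)
                l.run_var[...] = var.astype(np.float32)
                l.finalized = True

    def predict_proba(self, x: np.ndarray, batch: int = 32) -> np.ndarray:
        probs = []
        for lo in range(0, len(x), batch):
            logits = self.forward(x[lo:lo + batch], training=False)
            probs.append(softmax(logits, axis=1))
        return np.concatenate(probs, axis=0)

    # -- persistence ----------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrs: dict[str, np.ndarray] = {}
        for i, l in enumerate(self.layers):
            if l is None:
                continue
            for j, p in enumerate(l.params):
                arrs[f"l{i}p{j}"] = p
            if isinstance(l, _BatchNorm):
                arrs[f"l{i}rm"] = l.run_mean
                arrs[f"l{i}rv"] = l.run_var
        return arrs

    def _bn_meta(self) -> dict[str, np.ndarray]:
        return {f"l{i}meta": np.array([l.n_updates, int(l.finalized)])
                for i, l in enumerate(self.layers) if isinstance(l, _BatchNorm)}

    def save(self, path: str) -> None:
        np.savez(path, _spec=json.dumps({
            "input_size": self.spec.input_shape[0],
            "num_classes": self.spec.num_classes,
            "use_add": any(l.kind == "add" for l in self.spec.layers),
        }), **self.state_arrays(), **self._bn_meta())

    @classmethod
    def load(cls, path: str) -> "Network":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["_spec"]))
        net = cls(build_architecture(**meta))
        for key, arr in net.state_arrays().items():
            arr[...] = data[key]
        for i, l in enumerate(net.layers):
            if isinstance(l, _BatchNorm) and f"l{i}meta" in data:
                l.n_updates, fin = (int(v) for v in data[f"l{i}meta"])
                l.finalized = bool(fin)
        return net


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient wrt the logits."""
    p = softmax(logits, axis=1)
    B = len(y)
    loss = float(-np.log(np.clip(p[np.arange(B), y], 1e-12, None)).mean())
    d = p.copy()
    d[np.arange(B), y] -= 1.0
    return loss, (d / B).astype(np.float32)


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

#: per-optimizer hyperparameter defaults (learning rate alpha = 0.001 for all;
#: epsilon = 1e-6; Adadelta rho = 0.95, RMSProp rho = 0.9)
OPTIMIZER_DEFAULTS: dict[str, dict[str, float]] = {
    "sgdm":     dict(lr=0.001, momentum=0.9),
    "adam":     dict(lr=0.001, beta1=0.9, beta2=0.999, eps=1e-6),
    "adamax":   dict(lr=0.001, beta1=0.9, beta2=0.999, eps=1e-6),
    "adagrad":  dict(lr=0.001, eps=1e-6),
    "adadelta": dict(lr=0.001, rho=0.95, eps=1e-6),
    "rmsprop":  dict(lr=0.001, rho=0.9, eps=1e-6),
    "nadam":    dict(lr=0.001, beta1=0.9, beta2=0.999, eps=1e-6),
}


class Optimizer:
    def __init__(self, params: list[np.ndarray], **hp):
        self.params = params
        self.hp = hp
        self.t = 0
        self.state = [{} for _ in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, st in zip(self.params, grads, self.state):
            self._update(p, g.astype(np.float32), st)

    def _update(self, p, g, st):  # pragma: no cover - abstract
        raise NotImplementedError


class SGDM(Optimizer):
    def _update(self, p, g, st):
        v = st.setdefault("v", np.zeros_like(p))
        v[...] = self.hp["momentum"] * v - self.hp["lr"] * g
        p += v


class Adam(Optimizer):
    def _update(self, p, g, st):
        b1, b2, eps, lr = (self.hp[k] for k in ("beta1", "beta2", "eps", "lr"))
        m = st.setdefault("m", np.zeros_like(p))
        v = st.setdefault("v", np.zeros_like(p))
        m[...] = b1 * m + (1 - b1) * g
        v[...] = b2 * v + (1 - b2) * g * g
        mhat = m / (1 - b1**self.t)
        vhat = v / (1 - b2**self.t)
        p -= lr * mhat / (np.sqrt(vhat) + eps)


class AdaMax(Optimizer):
    def _update(self, p, g, st):
        b1, b2, eps, lr = (self.hp[k] for k in ("beta1", "beta2", "eps", "lr"))
        m = st.setdefault("m", np.zeros_like(p))
        u = st.setdefault("u", np.zeros_like(p))
        m[...] = b1 * m + (1 - b1) * g
        u[...] = np.maximum(b2 * u, np.abs(g))
        p -= (lr / (1 - b1**self.t)) * m / (u + eps)


class Adagrad(Optimizer):
    def _update(self, p, g, st):
        G = st.setdefault("G", np.zeros_like(p))
        G += g * g
        p -= self.hp["lr"] * g / (np.sqrt(G) + self.hp["eps"])


class Adadelta(Optimizer):
    def _update(self, p, g, st):
        rho, eps, lr = self.hp["rho"], self.hp["eps"], self.hp["lr"]
        Eg = st.setdefault("Eg", np.zeros_like(p))
        Ed = st.setdefault("Ed", np.zeros_like(p))
        Eg[...] = rho * Eg + (1 - rho) * g * g
        dx = np.sqrt(Ed + eps) / np.sqrt(Eg + eps) * g
        Ed[...] = rho * Ed + (1 - rho) * dx * dx
        p -= lr * dx


class RMSProp(Optimizer):
    def _update(self, p, g, st):
        rho, eps, lr = self.hp["rho"], self.hp["eps"], self.hp["lr"]
        Eg = st.setdefault("Eg", np.zeros_like(p))
        Eg[...] = rho * Eg + (1 - rho) * g * g
        p -= lr * g / (np.sqrt(Eg) + eps)


class Nadam(Optimizer):
    def _update(self, p, g, st):
        b1, b2, eps, lr = (self.hp[k] for k in ("beta1", "beta2", "eps", "lr"))
        m = st.setdefault("m", np.zeros_like(p))
        v = st.setdefault("v", np.zeros_like(p))
        m[...] = b1 * m + (1 - b1) * g
        v[...] = b2 * v + (1 - b2) * g * g
        mhat = m / (1 - b1**(self.t + 1))
        vhat = v / (1 - b2**self.t)
        p -= lr * (b1 * mhat + (1 - b1) * g / (1 - b1**self.t)) / (np.sqrt(vhat) + eps)


_OPTIMIZERS = {"sgdm": SGDM, "adam": Adam, "adamax": AdaMax, "adagrad": Adagrad,
               "adadelta": Adadelta, "rmsprop": RMSProp, "nadam": Nadam}


def make_optimizer(name: str, params: list[np.ndarray], **overrides) -> Optimizer:
    key = name.lower()
    if key not in _OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}")
    hp = {**OPTIMIZER_DEFAULTS[key], **overrides}
    return _OPTIMIZERS[key](params, **hp)


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    batch_size: int = 64
    epochs: int = 30
    folds: int = 5
    seed: int = 0
    input_size: int = 224
    optimizer_overrides: dict = field(default_factory=dict)
    augment: AugmentConfig | None = None   # applied to training folds only

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def kfold_split(labels, k: int, seed: int = 0,
                groups=None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition; optionally group-aware.

    Every index lands in exactly one test fold; per-class counts per fold
    differ by at most one.  When ``groups`` is given, all members of a group
    go to the same fold (stratified by the group's label).
    """
    y = np.asarray(labels)
    n = len(y)
    groups = np.arange(n) if groups is None else np.asarray(groups)
    rng = np.random.default_rng(seed)
    uniq, first = np.unique(groups, return_index=True)
    fold_of_group: dict = {}
    offset = 0   # rotates across classes so remainders spread over folds
    for cls in np.unique(y[first]):
        gids = uniq[y[first] == cls]
        gids = rng.permutation(gids)
        for i, gid in enumerate(gids):
            fold_of_group[gid] = (i + offset) % k
        offset += len(gids) % k
    fold_of = np.array([fold_of_group[g] for g in groups])
    return [(np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f))
            for f in range(k)]


@dataclass
class CrossValResult:
    fold_reports: list[MetricsReport]
    summary: dict[str, tuple[float | None, float | None]]
    histories: list[list[float]]          # per-fold loss curves
    oof_pred: np.ndarray | None = None    # out-of-fold class predictions


def _dataset_tensor(ds: LabeledDataset, size: int) -> np.ndarray:
    return np.stack([to_gray_stack(img, size) for img in ds.images])


def train_network(net: Network, X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
                  rng: np.random.Generator) -> list[float]:
    """Mini-batch cross-entropy training; returns the per-step loss history."""
    opt = make_optimizer(cfg.optimizer, net.parameters(), **cfg.optimizer_overrides)
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(len(X))
        for lo in range(0, len(X), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits = net.forward(X[idx], training=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"loss diverged (NaN/inf) under optimizer {cfg.optimizer!r}")
            net.backward(dlogits)
            opt.step(net.gradients())
            history.append(loss)
    net.finalize_bn(X, batch=cfg.batch_size)
    return history


def train_and_evaluate(ds: LabeledDataset, spec: ArchitectureSpec | None = None,
                       cfg: TrainConfig | None = None) -> CrossValResult:
    """Stratified k-fold training/evaluation of the lightweight CNN.

    Augmentation, when configured, is applied inside each training fold only,
    and augmented variants of one original never straddle folds (splits are
    group-aware on the original index).
    """
    cfg = cfg or TrainConfig()
    spec = spec or build_architecture(input_size=cfg.input_size)
    y = labels_to_int(ds.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training needs both classes present")
    folds = kfold_split(ds.labels, cfg.folds, seed=cfg.seed, groups=ds.groups)
    X_all = _dataset_tensor(ds, spec.input_shape[0])
    reports: list[MetricsReport] = []
    histories: list[list[float]] = []
    oof = np.zeros(len(ds), dtype=np.int64)
    for f, (tr, te) in enumerate(folds):
        rng = np.random.default_rng((cfg.seed, f))
        if cfg.augment is not None:
            sub = LabeledDataset(images=[ds.images[i] for i in tr],
                                 labels=[ds.labels[i] for i in tr])
            sub = augment_dataset(sub, replace(cfg.augment, seed=cfg.augment.seed + f))
            Xtr = _dataset_tensor(sub, spec.input_shape[0])
            ytr = labels_to_int(sub.labels)
        else:
            Xtr, ytr = X_all[tr], y[tr]
        net = Network(spec, seed=int(rng.integers(2**31)))
        hist = train_network(net, Xtr, ytr, cfg, rng)
        pred = net.predict_proba(X_all[te]).argmax(axis=1)
        oof[te] = pred
        rep = classification_metrics(confusion(pred, y[te], positive=1))
        logger.info("fold %d: acc=%s tpr=%s tnr=%s", f + 1,
                    rep.accuracy, rep.tpr, rep.tnr)
        reports.append(rep)
        histories.append(hist)
    return CrossValResult(fold_reports=reports,
                          summary=summarize_folds(reports),
                          histories=histories,
                          oof_pred=oof)
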