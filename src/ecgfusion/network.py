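"""Residual CNN with embedded frequency channel attention, in pure numpy.

Architecture (for fused 3-channel square beat images):

    stem conv (7x7 /2) -> max pool (3x3 /2)
    -> 4 Conv blocks, each:
         conv 3x3 -> BN -> FCA -> LeakyReLU -> conv 3x3 -> BN
         -> add shortcut h(x) -> LeakyReLU
       (identity shortcut when shapes match, 1x1 projection + BN otherwise)
    -> global average pool -> FC512 -> dropout -> FC64 -> dropout -> FC K
    -> softmax class probabilities.

Training uses label-smoothing cross-entropy, Adam, batch size 128 and a
best-validation-accuracy checkpoint.  All layers implement explicit
forward/backward passes in float32; convolution is im2col + GEMM, which is
fast enough on one CPU for the scaled-down problem sizes this package
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fca import FcaConfig, basis_stack

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainHistory",
    "ResNetFca",
    "build_model",
    "label_smoothing_loss",
    "train",
    "predict",
]

_F = np.float32


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    """Minimal layer protocol: forward/backward plus named parameters."""

    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]              # (N, C, OH, OW, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


class Conv2d(_Layer):
    def __init__(self, cin, cout, k, stride, pad, rng):
        super().__init__()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        std = np.sqrt(2.0 / (cin * k * k))
        self.params["w"] = rng.normal(0, std, (cout, cin * k * k)).astype(_F)
        self.grads["w"] = np.zeros_like(self.params["w"])

    def forward(self, x, training):
        self._xshape = x.shape
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._oh, self._ow = cols, oh, ow
        out = cols @ self.params["w"].T
        n = x.shape[0]
        return out.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, _, oh, ow = dout.shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.cout)
        self.grads["w"][...] = dmat.T @ self._cols
        dcols = dmat @ self.params["w"]
        k, s, p = self.k, self.stride, self.pad
        _, c, h, w = self._xshape
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_F)
        dcols = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, :, :, i, j]
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(_Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c, dtype=_F)
        self.params["beta"] = np.zeros(c, dtype=_F)
        self.grads["gamma"] = np.zeros(c, dtype=_F)
        self.grads["beta"] = np.zeros(c, dtype=_F)
        self.running_mean = np.zeros(c, dtype=_F)
        self.running_var = np.ones(c, dtype=_F)

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if training:
            self._xhat, self._invstd = xhat, invstd
        return self.params["gamma"][None, :, None, None] * xhat + \
            self.params["beta"][None, :, None, None]

    def backward(self, dout):
        xhat, invstd = self._xhat, self._invstd
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"][...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.params["gamma"][None, :, None, None]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (invstd[None, :, None, None] / n) * (
            n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )
        self._xhat = None
        return dx.astype(_F)


class LeakyReLU(_Layer):
    def __init__(self, slope=0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class MaxPool2d(_Layer):
    def __init__(self, k=3, stride=2, pad=1):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, training):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        n_, c_, oh, ow = win.shape[:4]
        flat = win.reshape(n, c, oh, ow, k * k)
        self._arg = flat.argmax(axis=-1)
        self._geom = (n, c, h, w, oh, ow)
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, h, w, oh, ow = self._geom
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_F)
        ii, jj = np.divmod(self._arg, k)
        oy, ox = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
        rows = oy[None, None] * s + ii
        cols = ox[None, None] * s + jj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (nn, cc, rows, cols), dout)
        return dxp[:, :, p : p + h, p : p + w]


class GlobalAvgPool(_Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).astype(_F)


class Linear(_Layer):
    def __init__(self, fin, fout, rng):
        super().__init__()
        std = np.sqrt(2.0 / fin)
        self.params["w"] = rng.normal(0, std, (fout, fin)).astype(_F)
        self.params["b"] = np.zeros(fout, dtype=_F)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self.grads["b"] = np.zeros_like(self.params["b"])

    def forward(self, x, training):
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dout):
        self.grads["w"][...] = dout.T @ self._x
        self.grads["b"][...] = dout.sum(axis=0)
        dx = dout @ self.params["w"]
        self._x = None
        return dx


class Dropout(_Layer):
    """Inverted dropout; the RNG is owned by the model for seeded training."""

    def __init__(self, p, model):
        super().__init__()
        self.p = p
        self._model = model

    def forward(self, x, training):
        if not training or self.p == 0:
            self._mask = None
            return x
        keep = (self._model.rng.random(x.shape) >= self.p).astype(_F) / (1 - self.p)
        self._mask = keep
        return x * keep

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class FcaAttention(_Layer):
    """Trainable FCA gate over a (N, C, H, W) feature map.

    The per-channel DCT basis is fixed; only the two bottleneck matrices
    W1 (C/r x C) and W2 (C x C/r) learn.  ``enabled=False`` turns the
    layer into the identity (the ablation lever).
    """

    def __init__(self, c, h, w, cfg: FcaConfig, rng, enabled=True):
        super().__init__()
        self.enabled = enabled
        if not enabled:
            return
        pairs = cfg.pairs(h, w)
        if c % len(pairs):
            raise ValueError(
                f"channels {c} not divisible by {len(pairs)} frequency groups"
            )
        basis = np.repeat(basis_stack(h, w, pairs), c // len(pairs), axis=0)
        self.basis = basis.astype(_F)  # (C, H, W)
        hidden = max(c // cfg.reduction, 1)
        self.params["w1"] = rng.normal(0, np.sqrt(2.0 / c), (hidden, c)).astype(_F)
        self.params["w2"] = rng.normal(0, np.sqrt(1.0 / hidden), (c, hidden)).astype(_F)
        self.grads["w1"] = np.zeros_like(self.params["w1"])
        self.grads["w2"] = np.zeros_like(self.params["w2"])

    def forward(self, x, training):
        if not self.enabled:
            return x
        z = np.einsum("nchw,chw->nc", x, self.basis)
        h1 = z @ self.params["w1"].T
        hr = np.maximum(h1, 0.0)
        s = hr @ self.params["w2"].T
        a = np.where(s >= 0, 1.0 / (1.0 + np.exp(-np.abs(s))),
                     np.exp(-np.abs(s)) / (1.0 + np.exp(-np.abs(s))))
        self._cache = (x, z, h1, hr, a)
        return x * a[:, :, None, None]

    def backward(self, dout):
        if not self.enabled:
            return dout
        x, z, h1, hr, a = self._cache
        da = (dout * x).sum(axis=(2, 3))
        ds = da * a * (1 - a)
        self.grads["w2"][...] = ds.T @ hr
        dhr = ds @ self.params["w2"]
        dh1 = dhr * (h1 > 0)
        self.grads["w1"][...] = dh1.T @ z
        dz = dh1 @ self.params["w1"]
        dx = dout * a[:, :, None, None] + dz[:, :, None, None] * self.basis[None]
        self._cache = None
        return dx.astype(_F)


class _ConvBlock:
    """conv-BN-FCA-LeakyReLU-conv-BN + shortcut, post-addition activation."""

    def __init__(self, cin, cout, stride, size, fca_cfg, slope, rng, fca_enabled):
        out_size = (size + 2 - 3) // stride + 1
        self.conv1 = Conv2d(cin, cout, 3, stride, 1, rng)
        self.bn1 = BatchNorm2d(cout)
        self.fca = FcaAttention(cout, out_size, out_size, fca_cfg, rng, fca_enabled)
        self.act1 = LeakyReLU(slope)
        self.conv2 = Conv2d(cout, cout, 3, 1, 1, rng)
        self.bn2 = BatchNorm2d(cout)
        self.act2 = LeakyReLU(slope)
        self.out_size = out_size
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, stride, 0, rng)
            self.proj_bn = BatchNorm2d(cout)
        else:
            self.proj = None

    def layers(self):
        ls = [self.conv1, self.bn1, self.fca, self.act1, self.conv2, self.bn2, self.act2]
        if self.proj is not None:
            ls += [self.proj, self.proj_bn]
        return ls

    def forward(self, x, training):
        y = self.conv1.forward(x, training)
        y = self.bn1.forward(y, training)
        y = self.fca.forward(y, training)
        y = self.act1.forward(y, training)
        y = self.conv2.forward(y, training)
        y = self.bn2.forward(y, training)
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x, training), training)
        else:
            sc = x
        return self.act2.forward(y + sc, training)

    def backward(self, dout):
        d = self.act2.backward(dout)
        dsc = d
        dy = self.bn2.backward(d)
        dy = self.conv2.backward(dy)
        dy = self.act1.backward(dy)
        dy = self.fca.backward(dy)
        dy = self.bn1.backward(dy)
        dx = self.conv1.backward(dy)
        if self.proj is not None:
            dx = dx + self.proj.backward(self.proj_bn.backward(dsc))
        else:
            dx = dx + dsc
        return dx


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The published description fixes the topology (stem + pool + four Conv
    blocks with FCA, FC512/FC64 with 0.5 dropout, 5-way softmax) but not
    the widths; the defaults follow standard residual-network conventions
    and every width is configurable.  ``block_repeats`` exposes the depth
    ablation (blocks per stage).
    """

    input_channels: int = 3
    image_size: int = 224
    stem_kernel: int = 7
    stem_stride: int = 2
    stem_channels: int = 64
    pool_kernel: int = 3
    pool_stride: int = 2
    block_channels: tuple = (64, 128, 256, 512)
    block_strides: tuple = (1, 2, 2, 2)
    block_repeats: tuple = (1, 1, 1, 1)
    leaky_slope: float = 0.01
    fc_dims: tuple = (512, 64)
    dropout_p: float = 0.5
    n_classes: int = 5
    fca: FcaConfig = field(default_factory=FcaConfig)
    fca_enabled: bool = True

    def validate(self):
        if len(self.block_channels) != 4 or len(self.block_strides) != 4 \
                or len(self.block_repeats) != 4:
            raise ValueError("the architecture has exactly 4 Conv-block stages")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for c in self.block_channels:
            if c % self.fca.n_freq and self.fca.strategy == "lowest":
                raise ValueError(
                    f"block width {c} not divisible by fca.n_freq={self.fca.n_freq}"
                )


@dataclass
class TrainConfig:
    """Optimisation settings (batch 128, Adam, label smoothing, <=80 epochs,
    best-validation-accuracy checkpointing)."""

    batch_size: int = 128
    max_epochs: int = 80
    learning_rate: float = 1e-3
    label_smoothing_eps: float = 0.1
    seed: int = 0

    def validate(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0 <= self.label_smoothing_eps < 1:
            raise ValueError("label_smoothing_eps must lie in [0, 1)")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    best_epoch: int = -1


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class ResNetFca:
    """The assembled network; see the module docstring for the topology."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.rng = np.random.default_rng(seed + 1)  # dropout stream
        slope = config.leaky_slope

        self.stem = Conv2d(config.input_channels, config.stem_channels,
                           config.stem_kernel, config.stem_stride,
                           config.stem_kernel // 2, rng)
        self.stem_bn = BatchNorm2d(config.stem_channels)
        self.stem_act = LeakyReLU(slope)
        self.pool = MaxPool2d(config.pool_kernel, config.pool_stride, 1)

        size = (config.image_size + 2 * (config.stem_kernel // 2)
                - config.stem_kernel) // config.stem_stride + 1
        size = (size + 2 - config.pool_kernel) // config.pool_stride + 1

        self.blocks: list[_ConvBlock] = []
        cin = config.stem_channels
        for cout, stride, reps in zip(config.block_channels,
                                      config.block_strides,
                                      config.block_repeats):
            for r in range(reps):
                blk = _ConvBlock(cin, cout, stride if r == 0 else 1, size,
                                 config.fca, slope, rng, config.fca_enabled)
                size = blk.out_size
                self.blocks.append(blk)
                cin = cout
        if size < 1:
            raise ValueError("image_size too small for this architecture")

        self.gap = GlobalAvgPool()
        self.fc1 = Linear(cin, config.fc_dims[0], rng)
        self.fc1_act = LeakyReLU(slope)
        self.drop1 = Dropout(config.dropout_p, self)
        self.fc2 = Linear(config.fc_dims[0], config.fc_dims[1], rng)
        self.fc2_act = LeakyReLU(slope)
        self.drop2 = Dropout(config.dropout_p, self)
        self.head = Linear(config.fc_dims[1], config.n_classes, rng)

    # -- plumbing ---------------------------------------------------------

    def _layers(self):
        ls = [self.stem, self.stem_bn, self.stem_act, self.pool]
        for b in self.blocks:
            ls += b.layers()
        ls += [self.gap, self.fc1, self.fc1_act, self.drop1,
               self.fc2, self.fc2_act, self.drop2, self.head]
        return ls

    def parameters(self):
        out = []
        for i, layer in enumerate(self._layers()):
            for name, p in layer.params.items():
                out.append((f"{i}.{name}", p, layer.grads[name]))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for _, p, _ in self.parameters())

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self._layers()):
            for name, p in layer.params.items():
                state[f"{i}.{name}"] = p.copy()
            if isinstance(layer, BatchNorm2d):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict):
        for i, layer in enumerate(self._layers()):
            for name in layer.params:
                layer.params[name][...] = state[f"{i}.{name}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a (N, C, H, W) batch."""
        x = np.ascontiguousarray(x, dtype=_F)
        if x.ndim != 4 or x.shape[1] != self.config.input_channels \
                or x.shape[2] != self.config.image_size:
            raise ValueError(
                f"expected (N, {self.config.input_channels}, "
                f"{self.config.image_size}, {self.config.image_size}) input, "
                f"got {x.shape}"
            )
        h = self.stem_act.forward(
            self.stem_bn.forward(self.stem.forward(x, training), training), training
        )
        h = self.pool.forward(h, training)
        for blk in self.blocks:
            h = blk.forward(h, training)
        h = self.gap.forward(h, training)
        h = self.drop1.forward(
            self.fc1_act.forward(self.fc1.forward(h, training), training), training
        )
        h = self.drop2.forward(
            self.fc2_act.forward(self.fc2.forward(h, training), training), training
        )
        return self.head.forward(h, training)

    def backward(self, dlogits: np.ndarray):
        d = self.head.backward(dlogits.astype(_F))
        d = self.fc2_act.backward(self.drop2.backward(d))
        d = self.fc2.backward(d)
        d = self.fc1_act.backward(self.drop1.backward(d))
        d = self.fc1.backward(d)
        d = self.gap.backward(d)
        for blk in reversed(self.blocks):
            d = blk.backward(d)
        d = self.pool.backward(d)
        d = self.stem_act.backward(d)
        d = self.stem_bn.backward(d)
        self.stem.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax class probabilities in evaluation mode."""
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], training=False)
            out.append(_softmax(logits))
        return np.concatenate(out, axis=0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(config: ModelConfig | None = None, seed: int = 0):
    """Construct the network; returns (model, parameter_count)."""
    model = ResNetFca(config or ModelConfig(), seed=seed)
    return model, model.n_parameters()


# ---------------------------------------------------------------------------
# loss / training
# ---------------------------------------------------------------------------

def label_smoothing_loss(probs: np.ndarray, targets: np.ndarray, eps: float = 0.1) -> float:
    """Cross-entropy against (1-eps)*onehot + eps/K smoothed targets.

    ``probs`` are strictly positive simplex rows; a 1e-12 floor guards the
    logarithm.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    targets = np.atleast_1d(np.asarray(targets))
    n, k = probs.shape
    logp = np.log(np.maximum(probs, 1e-12))
    smooth = -(eps / k) * logp.sum(axis=1)
    hard = -(1 - eps) * logp[np.arange(n), targets]
    return float((smooth + hard).mean())


class _Adam:
    def __init__(self, model: ResNetFca, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p) for k, p, _ in model.parameters()}
        self.v = {k: np.zeros_like(p) for k, p, _ in model.parameters()}

    def step(self, model: ResNetFca):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, p, g in model.parameters():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train(
    model: ResNetFca,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    tcfg: TrainConfig | None = None,
    verbose: bool = False,
) -> TrainHistory:
    """Train in place and restore the best-validation-accuracy checkpoint.

    Fully seeded: data order and dropout masks derive from ``tcfg.seed``.
    Raises ``RuntimeError`` on a non-finite loss.
    """
    tcfg = tcfg or TrainConfig()
    tcfg.validate()
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be nonempty")
    y_train = np.asarray(y_train, dtype=np.intp)
    y_val = np.asarray(y_val, dtype=np.intp)
    k = model.config.n_classes
    if len(np.unique(y_train)) < k:
        import warnings
        warnings.warn("some classes are absent from the training set", stacklevel=2)

    rng = np.random.default_rng(tcfg.seed)
    model.rng = np.random.default_rng(rng.integers(2**31))
    opt = _Adam(model, tcfg.learning_rate)
    hist = TrainHistory()
    best_acc, best_state = -1.0, None
    eps = tcfg.label_smoothing_eps

    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), tcfg.batch_size):
            idx = order[i : i + tcfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            probs = _softmax(model.forward(xb, training=True))
            loss = label_smoothing_loss(probs, yb, eps)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            smooth = np.full_like(probs, eps / k)
            smooth[np.arange(len(yb)), yb] += 1 - eps
            model.backward((probs - smooth) / len(yb))
            opt.step(model)
            losses.append(loss)

        val_probs = model.predict_proba(x_val)
        val_loss = label_smoothing_loss(val_probs, y_val, eps)
        val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(val_loss)
        hist.val_accuracy.append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
            hist.best_epoch = epoch
        if verbose:
            print(f"epoch {epoch:3d}  train_loss {hist.train_loss[-1]:.4f}  "
                  f"val_loss {val_loss:.4f}  val_acc {val_acc:.4f}")

    if best_state is not None:
        model.load_state_dict(best_state)
    return hist


def predict(model: ResNetFca, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation-mode class probabilities and argmax labels."""
    probs = model.predict_proba(x)
    return probs, probs.argmax(axis=1)
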