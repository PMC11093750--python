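"""The steering network: a compact NumPy 3D CNN with a dropout head.

Architecture contract: a stack of strided 3D convolutions, a single dropout
layer (rate 0.5) after the conv stack, three fully connected layers and a
linear head with three outputs — the two Bishop steering curvatures and the
distance to membrane along the flight direction.  Keeping the sole dropout
layer after the convolutions means Monte-Carlo-dropout inference can share
the whole conv stack across samples, so M stochastic passes cost barely
more than one (``count_flops`` quantifies this).

Layers, initialization (He for hidden layers, Glorot for the linear head),
the MSE + L2 loss, and the Adam / RMSProp-with-momentum optimizers are all
implemented here on top of NumPy; forward and backward passes use im2col
reshapes so the work lands in BLAS matmuls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .geometry import Steering
from .sampling import AlignedPatch

__all__ = [
    "SteeringNetConfig",
    "TrainConfig",
    "MCSamples",
    "SteeringNet",
    "build_and_init",
    "train",
    "predict",
    "predict_symmetrized",
    "mc_predict",
    "count_flops",
    "reference_config",
    "test_scale_config",
    "augment_sample",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SteeringNetConfig:
    """Architecture description.

    The reference profile uses seven strided conv layers on a 96x96x16
    input; a reduced test-scale profile (four conv layers, 48x48x8 input)
    trains in minutes on one CPU core and is used throughout the test
    fixtures.  ``output_scale`` multiplies curvature targets before the loss
    so the three outputs share dynamic range (membrane distance is in um,
    curvatures in 1/um).
    """

    input_shape: tuple[int, int, int] = (96, 96, 16)
    conv_channels: tuple[int, ...] = (24, 32, 48, 64, 96, 128, 128)
    conv_strides: tuple[tuple[int, int, int], ...] = (
        (2, 2, 1), (2, 2, 1), (2, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 1),
    )
    kernel: tuple[int, int, int] = (3, 3, 3)
    activation: str = "elu"
    dropout_rate: float = 0.5
    fc_widths: tuple[int, ...] = (96, 64, 48)
    output_dim: int = 3
    output_scale: float = 0.5  # = p/2 for the default 1 um projection plane

    def __post_init__(self):
        if len(self.conv_channels) != len(self.conv_strides):
            raise ValueError("conv_channels and conv_strides must have equal length")
        if self.activation not in ("elu", "relu"):
            raise ValueError("activation must be 'elu' or 'relu'")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if len(self.fc_widths) != 3:
            raise ValueError("exactly three fully connected layers are required")

    def conv_output_shapes(self) -> list[tuple[int, int, int]]:
        shape = self.input_shape
        out = []
        for s in self.conv_strides:
            shape = tuple(int(np.ceil(d / st)) for d, st in zip(shape, s))
            out.append(shape)
        return out

    @property
    def flat_features(self) -> int:
        return int(np.prod(self.conv_output_shapes()[-1])) * self.conv_channels[-1]


def reference_config() -> SteeringNetConfig:
    """Full-scale architecture: seven strided convs reduce 96x96x16 to 1x1x1x128."""
    return SteeringNetConfig()


def test_scale_config(dropout_rate: float = 0.5, activation: str = "elu") -> SteeringNetConfig:
    """Reduced profile for CPU-scale experiments: 48x48x8 input, four convs."""
    return SteeringNetConfig(
        input_shape=(48, 48, 8),
        conv_channels=(8, 16, 24, 32),
        conv_strides=((2, 2, 2), (2, 2, 2), (2, 2, 1), (2, 2, 1)),
        fc_widths=(48, 32, 24),
        dropout_rate=dropout_rate,
        activation=activation,
    )


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    optimizer: str = "adam"  # or "rmsprop_momentum"
    learning_rate: float = 1e-4
    lr_final: float | None = None  # linear decay target; None = constant
    l2_coeff: float = 1e-5
    max_updates: int = 1000
    momentum: float = 0.9
    seed: int = 0
    augment: bool = True

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in ("adam", "rmsprop_momentum"):
            raise ValueError("unknown optimizer")


@dataclass
class MCSamples:
    """Monte-Carlo-dropout curvature samples at one pose/orientation."""

    curvature_samples: np.ndarray  # (M, 2)
    membrane_samples: np.ndarray | None = None

    @property
    def M(self) -> int:
        return len(self.curvature_samples)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


def _same_pad(in_size: int, k: int, stride: int) -> tuple[int, int, int]:
    out = int(np.ceil(in_size / stride))
    total = max((out - 1) * stride + k - in_size, 0)
    return out, total // 2, total - total // 2


class _Conv3D:
    def __init__(self, c_in, c_out, kernel, stride, rng, gain=2.0):
        fan_in = c_in * int(np.prod(kernel))
        self.W = rng.normal(0.0, np.sqrt(gain / fan_in), size=(c_out, c_in, *kernel)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel = kernel
        self.stride = stride

    def out_shape(self, in_shape):
        return tuple(
            _same_pad(d, k, s)[0] for d, k, s in zip(in_shape, self.kernel, self.stride)
        )

    def _pad(self, x):
        pads = [(0, 0), (0, 0)]
        for d, k, s in zip(x.shape[2:], self.kernel, self.stride):
            _, lo, hi = _same_pad(d, k, s)
            pads.append((lo, hi))
        return np.pad(x, pads), pads

    def forward(self, x):
        xp, pads = self._pad(x)
        k = self.kernel
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=(2, 3, 4))
        sx, sy, sz = self.stride
        win = win[:, :, ::sx, ::sy, ::sz]  # (N, Cin, ox, oy, oz, kx, ky, kz)
        n, c_in, ox, oy, oz = win.shape[:5]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            n * ox * oy * oz, -1
        )
        Wm = self.W.reshape(self.W.shape[0], -1)
        out = cols @ Wm.T + self.b
        out = out.reshape(n, ox, oy, oz, -1).transpose(0, 4, 1, 2, 3)
        self._cache = (x.shape, xp.shape, pads, cols, (n, ox, oy, oz))
        return np.ascontiguousarray(out)

    def backward(self, dout, need_dx: bool = True):
        x_shape, xp_shape, pads, cols, (n, ox, oy, oz) = self._cache
        c_out = self.W.shape[0]
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 4, 1)).reshape(-1, c_out)
        self.dW = (dflat.T @ cols).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        if not need_dx:
            return None
        Wm = self.W.reshape(c_out, -1)
        dcols = dflat @ Wm  # (N*P, Cin*k^3)
        k = self.kernel
        dcols = np.ascontiguousarray(
            dcols.reshape(n, ox, oy, oz, -1, *k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
        )
        dxp = np.zeros(xp_shape, dtype=np.float32)
        sx, sy, sz = self.stride
        for a in range(k[0]):
            for b in range(k[1]):
                for c in range(k[2]):
                    dxp[:, :, a : a + ox * sx : sx, b : b + oy * sy : sy,
                        c : c + oz * sz : sz] += dcols[..., a, b, c]
        sl = tuple(
            slice(p[0], dim - p[1]) for p, dim in zip(pads[2:], xp_shape[2:])
        )
        return dxp[:, :, sl[0], sl[1], sl[2]]

    @property
    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


class _Dense:
    def __init__(self, n_in, n_out, rng, init="he", gain=2.0):
        if init == "he":
            self.W = rng.normal(0.0, np.sqrt(gain / n_in), size=(n_in, n_out)).astype(
                np.float32
            )
        else:  # glorot uniform for the linear head
            lim = np.sqrt(6.0 / (n_in + n_out))
            self.W = rng.uniform(-lim, lim, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    @property
    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


def _act(x, kind):
    if kind == "relu":
        return np.maximum(x, 0.0)
    out = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
    return out.astype(np.float32)


def _act_grad(x, y, kind):
    if kind == "relu":
        return (x > 0).astype(np.float32)
    return np.where(x > 0, 1.0, y + 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class SteeringNet:
    """Conv stack -> dropout -> 3 FC layers -> linear head (k1, k2, d_membrane)."""

    def __init__(self, cfg: SteeringNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.convs: list[_Conv3D] = []
        c_in = 1
        for c_out, stride in zip(cfg.conv_channels, cfg.conv_strides):
            self.convs.append(_Conv3D(c_in, c_out, cfg.kernel, stride, rng))
            c_in = c_out
        n_in = cfg.flat_features
        self.fcs: list[_Dense] = []
        for w in cfg.fc_widths:
            self.fcs.append(_Dense(n_in, w, rng, init="he"))
            n_in = w
        self.head = _Dense(n_in, cfg.output_dim, rng, init="glorot")

    # -- forward pieces ------------------------------------------------------

    def conv_features(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """Run the conv stack; x is (N, A, B, C) -> flat features (N, F)."""
        h = x[:, None].astype(np.float32)
        self._conv_pre = []
        self._conv_post = []
        for conv in self.convs:
            z = conv.forward(h)
            h = _act(z, self.cfg.activation)
            if cache:
                self._conv_pre.append(z)
                self._conv_post.append(h)
        return h.reshape(h.shape[0], -1)

    def head_forward(self, feats: np.ndarray, cache: bool = False) -> np.ndarray:
        h = feats
        self._fc_pre = []
        self._fc_post = []
        for fc in self.fcs:
            z = fc.forward(h)
            h = _act(z, self.cfg.activation)
            if cache:
                self._fc_pre.append(z)
                self._fc_post.append(h)
        return self.head.forward(h)

    def forward(self, x, train=False, rng=None):
        feats = self.conv_features(x, cache=train)
        if train and self.cfg.dropout_rate > 0:
            keep = 1.0 - self.cfg.dropout_rate
            mask = (rng.uniform(size=feats.shape) < keep).astype(np.float32) / keep
            self._drop_mask = mask
            feats_d = feats * mask
        else:
            self._drop_mask = None
            feats_d = feats
        self._feats = feats
        return self.head_forward(feats_d, cache=train)

    def backward(self, dout):
        h = self.head.backward(dout)
        for fc, z, y in zip(reversed(self.fcs), reversed(self._fc_pre),
                            reversed(self._fc_post)):
            h = h * _act_grad(z, y, self.cfg.activation)
            # note: _Dense.backward uses its cached input
            h = fc.backward(h)
        if self._drop_mask is not None:
            h = h * self._drop_mask
        last = self._conv_post[-1]
        h = h.reshape(last.shape)
        for i, (conv, z, y) in enumerate(
            zip(reversed(self.convs), reversed(self._conv_pre),
                reversed(self._conv_post))
        ):
            h = h * _act_grad(z, y, self.cfg.activation)
            # the input gradient of the first conv layer is never consumed
            h = conv.backward(h, need_dx=i < len(self.convs) - 1)
        return h

    # -- parameter access ----------------------------------------------------

    def layers(self):
        return [*self.convs, *self.fcs, self.head]

    def parameters(self):
        out = []
        for layer in self.layers():
            out.extend(p for _, p in layer.params)
        return out

    def gradients(self):
        out = []
        for layer in self.layers():
            out.extend(layer.grads())
        return out

    def l2_penalty(self):
        return sum(float((p**2).sum()) for p in self.parameters())

    def state_dict(self):
        return {f"p{i}": p.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, d):
        for i, p in enumerate(self.parameters()):
            p[...] = d[f"p{i}"]


def build_and_init(cfg: SteeringNetConfig, seed: int = 0) -> SteeringNet:
    """Instantiate the network with He-initialized hidden layers and a Glorot head."""
    return SteeringNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class _RMSPropMomentum:
    def __init__(self, params, lr, decay=0.9, momentum=0.9, eps=1e-8):
        self.params = params
        self.lr, self.decay, self.momentum, self.eps = lr, decay, momentum, eps
        self.sq = [np.zeros_like(p) for p in params]
        self.mom = [np.zeros_like(p) for p in params]

    def step(self, grads):
        for p, g, s, m in zip(self.params, grads, self.sq, self.mom):
            s[...] = self.decay * s + (1 - self.decay) * g * g
            m[...] = self.momentum * m + self.lr * g / (np.sqrt(s) + self.eps)
            p -= m


# ---------------------------------------------------------------------------
# Augmentation (tangential-rotation / flip invariance)
# ---------------------------------------------------------------------------


def augment_sample(
    patch: np.ndarray, target: np.ndarray, rot_quarter: int, flip: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a quarter-turn rotation about t and an optional flip of n2.

    These are exact invariance transformations of the steering problem: the
    patch axes permute/reverse and the curvature targets co-rotate
    (90 deg: (k1, k2) -> (k2, -k1); flip: k2 -> -k2).  The membrane-distance
    target is invariant.
    """
    p = patch
    k1, k2, dm = float(target[0]), float(target[1]), float(target[2])
    for _ in range(rot_quarter % 4):
        # new n1 = old n2, new n2 = -old n1  =>  new[a, b] = old[A-1-b, a]
        p = p[::-1, :, :].transpose(1, 0, 2)
        k1, k2 = k2, -k1
    if flip:
        p = p[:, ::-1, :]
        k2 = -k2
    return np.ascontiguousarray(p), np.array([k1, k2, dm], dtype=target.dtype)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------


def train(
    net: SteeringNet,
    patches: np.ndarray,
    targets: np.ndarray,
    cfg: TrainConfig,
    val_patches: np.ndarray | None = None,
    val_targets: np.ndarray | None = None,
    val_every: int = 0,
):
    """Train on (patch, target) arrays minimizing MSE + L2.

    ``targets`` rows are (k1, k2, membrane_distance) in physical units; the
    curvature components are scaled by ``cfg_net.output_scale`` inside the
    loss so the three outputs share dynamic range.  Returns a history dict
    with per-update losses (and periodic validation MSE when requested).
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(patches)
    scale = np.array([net.cfg.output_scale, net.cfg.output_scale, 1.0], dtype=np.float32)
    y = targets.astype(np.float32) * scale
    history = {"loss": [], "mse": [], "l2": [], "val_updates": [], "val_mse": []}
    if cfg.optimizer == "adam":
        opt = _Adam(net.parameters(), cfg.learning_rate)
    else:
        opt = _RMSPropMomentum(net.parameters(), cfg.learning_rate, momentum=cfg.momentum)

    for update in range(cfg.max_updates):
        if cfg.batch_size >= n:
            idx = np.arange(n)
        else:
            idx = rng.integers(0, n, size=cfg.batch_size)
        xb = patches[idx].astype(np.float32)
        yb = y[idx].copy()
        if cfg.augment:
            rots = rng.integers(0, 4, size=len(idx))
            flips = rng.integers(0, 2, size=len(idx)).astype(bool)
            xb = xb.copy()
            for i in range(len(idx)):
                if rots[i] or flips[i]:
                    yi = yb[i] / scale
                    xb[i], yi = augment_sample(xb[i], yi, int(rots[i]), bool(flips[i]))
                    yb[i] = yi * scale
        out = net.forward(xb, train=True, rng=rng)
        err = out - yb
        mse = float((err**2).mean())
        l2 = net.l2_penalty()
        loss = mse + cfg.l2_coeff * l2
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at update {update}: mse={mse}")
        dout = (2.0 / err.size) * err.astype(np.float32)
        net.backward(dout)
        grads = net.gradients()
        if cfg.l2_coeff:
            grads = [g + 2.0 * cfg.l2_coeff * p for g, p in zip(grads, net.parameters())]
        if cfg.lr_final is not None and cfg.max_updates > 1:
            frac = update / (cfg.max_updates - 1)
            opt.lr = cfg.learning_rate + frac * (cfg.lr_final - cfg.learning_rate)
        opt.step(grads)
        history["loss"].append(loss)
        history["mse"].append(mse)
        history["l2"].append(l2)
        if val_every and val_patches is not None and (update + 1) % val_every == 0:
            vo = _forward_eval(net, val_patches)
            vmse = float(((vo - val_targets.astype(np.float32) * scale) ** 2).mean())
            history["val_updates"].append(update + 1)
            history["val_mse"].append(vmse)
    return net, history


def _forward_eval(net: SteeringNet, patches: np.ndarray, batch: int = 64) -> np.ndarray:
    outs = []
    for i in range(0, len(patches), batch):
        feats = net.conv_features(patches[i : i + batch].astype(np.float32))
        outs.append(net.head_forward(feats))
    return np.concatenate(outs, axis=0)


def predict(net: SteeringNet, patch: AlignedPatch | np.ndarray) -> Steering:
    """Deterministic (dropout-expectation) prediction for one patch."""
    x = patch.intensities if isinstance(patch, AlignedPatch) else patch
    if x.shape != net.cfg.input_shape:
        raise ValueError(f"patch shape {x.shape} != net input {net.cfg.input_shape}")
    out = _forward_eval(net, x[None])[0]
    s = net.cfg.output_scale
    return Steering(float(out[0]) / s, float(out[1]) / s,
                    membrane_distance=max(float(out[2]), 0.0))


def predict_symmetrized(net: SteeringNet, patch: AlignedPatch | np.ndarray) -> Steering:
    """Prediction averaged over the 8 exact symmetries of the steering problem.

    Quarter-turn rotations about the tangent and the normal flip are
    invariance transformations; evaluating the network on all 8 transformed
    patches and mapping the predicted curvatures back before averaging
    symmetrizes the estimator and reduces its variance at 8x the head cost
    (the patch transforms are pure index permutations).
    """
    x = patch.intensities if isinstance(patch, AlignedPatch) else patch
    if x.shape != net.cfg.input_shape:
        raise ValueError(f"patch shape {x.shape} != net input {net.cfg.input_shape}")
    batch = []
    transforms = []
    dummy = np.zeros(3)
    for rot in range(4):
        for flip in (False, True):
            xt, _ = augment_sample(x, dummy, rot, flip)
            batch.append(xt)
            transforms.append((rot, flip))
    out = _forward_eval(net, np.asarray(batch))
    s = net.cfg.output_scale
    k1s, k2s, dms = [], [], []
    for (rot, flip), o in zip(transforms, out):
        k1, k2 = float(o[0]) / s, float(o[1]) / s
        # invert the target transform: flip first, then rotate back
        if flip:
            k2 = -k2
        for _ in range(rot):
            k1, k2 = -k2, k1  # inverse of (k1, k2) -> (k2, -k1)
        k1s.append(k1)
        k2s.append(k2)
        dms.append(float(o[2]))
    return Steering(float(np.mean(k1s)), float(np.mean(k2s)),
                    membrane_distance=max(float(np.mean(dms)), 0.0))


def mc_predict(
    net: SteeringNet, patch: AlignedPatch | np.ndarray, M: int = 128, seed: int = 0
) -> MCSamples:
    """Monte-Carlo-dropout sampling: conv features computed once, M dropout masks.

    Only the (cheap) fully connected head is recomputed per sample; this is
    what keeps the FLOP overhead of uncertainty estimation negligible.
    """
    if M < 2:
        raise ValueError("M must be >= 2 for covariance estimation")
    x = patch.intensities if isinstance(patch, AlignedPatch) else patch
    feats = net.conv_features(x[None])  # (1, F)
    rate = net.cfg.dropout_rate
    rng = np.random.default_rng(seed)
    if rate > 0:
        keep = 1.0 - rate
        masks = (rng.uniform(size=(M, feats.shape[1])) < keep).astype(np.float32) / keep
        h = feats * masks
    else:
        h = np.repeat(feats, M, axis=0)
    out = net.head_forward(h)
    s = net.cfg.output_scale
    return MCSamples(out[:, :2].astype(float) / s,
                     np.maximum(out[:, 2].astype(float), 0.0))


# ---------------------------------------------------------------------------
# FLOP accounting
# ---------------------------------------------------------------------------


def count_flops(cfg: SteeringNetConfig, M: int = 128) -> tuple[float, float, float]:
    """FLOPs of one standard pass, one M-sample MC-dropout pass, and the overhead.

    A multiply-accumulate counts as 2 FLOPs.  The MC pass shares the conv
    stack and repeats only the fully connected head per dropout mask:
    mc = conv + M * head; overhead = (mc - single) / single.
    """
    conv_flops = 0.0
    c_in = 1
    kv = int(np.prod(cfg.kernel))
    for c_out, shape in zip(cfg.conv_channels, cfg.conv_output_shapes()):
        conv_flops += float(np.prod(shape)) * c_out * c_in * kv * 2.0
        c_in = c_out
    head_flops = 0.0
    n_in = cfg.flat_features
    for w in (*cfg.fc_widths, cfg.output_dim):
        head_flops += n_in * w * 2.0
        n_in = w
    single = conv_flops + head_flops
    mc = conv_flops + M * head_flops
    return single, mc, (mc - single) / single
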