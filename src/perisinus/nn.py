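"""3D U-Net cascade: models, losses, augmentation, training, prediction.

The two networks share one architecture derived from the 3D U-Net:
per level two blocks of (batch norm -> 3x3x3 convolution -> ReLU), max
pooling 2x2x2 between levels, transposed-convolution (kernel and stride
2x2x2) up-sampling with skip concatenation, and a 1x1x1 convolution +
softmax head.  ``FCNN_mask`` is a 2-class single-channel model trained
with cross entropy; ``FCNN_labels`` is a 4-class two-channel model
(z-scored image + pre-label map) trained with generalized Dice loss.

Everything is implemented in NumPy (float32, channels-last layout
``(batch, x, y, z, channel)``): convolutions are evaluated as one BLAS
GEMM per kernel offset, and gradients are derived by hand.  This keeps
the package dependency-light, bit-reproducible under a fixed seed, and
fast enough for phantom-scale experiments on a single CPU.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from .atlas import extract_patch, inference_patch_origins, stitch_predictions
from .preprocess import zscore_array, zscore_patch
from .volumes import PATCH_SHAPE, LabelMap, Patch, Volume3D

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "UNet3D",
    "build_unet",
    "loss_ce",
    "loss_gdl",
    "augment_flip",
    "augment_noise",
    "augment_clahe",
    "TrainingSample",
    "train",
    "predict_mask",
    "predict_labels",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

_OFFSETS3 = [(di, dj, dk) for di in range(3) for dj in range(3) for dk in range(3)]
_OFFSETS2 = [(di, dj, dk) for di in range(2) for dj in range(2) for dk in range(2)]

CE_EPS = 1e-7
GDL_EPS = 1e-6


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class UNetConfig:
    in_channels: int = 1
    out_classes: int = 2
    levels: int = 3
    base_channels: int = 16
    seed: int = 0

    def check_shape(self, spatial: Sequence[int]) -> None:
        div = 2 ** (self.levels - 1)
        if any(s % div for s in spatial):
            raise ValueError(
                f"patch shape {tuple(spatial)} not divisible by {div} "
                f"(levels={self.levels})"
            )


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    The optimizer is Adam with learning rate 1e-4 by default; phantom-
    scale runs typically raise the rate and cut epochs (see docs).
    """

    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 2
    seed: int = 0
    loss: str = "ce"               # "ce" | "gdl"
    weight_power: int = 2          # generalized-Dice class-weight exponent
    augment_flip: bool = True
    augment_noise: bool = True
    noise_sd_max: float = 0.1      # in z-score units
    augment_clahe: bool = False
    clahe_clip: float = 0.01
    clahe_tiles: int = 8
    shuffle: bool = True
    early_stop_patience: int = 10  # only used when a validation set is given
    val_metric: str = "loss"       # "loss" | "macro_dice" (model selection)
    head_prior_init: bool = True   # CE only; disable when resuming training
    class_weight_power: float = 0.0  # CE only: median-frequency balancing
    # exponent (0 = unweighted, 1 = full median-frequency weights)

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("ce", "gdl"):
            raise ValueError("loss must be 'ce' or 'gdl'")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    """Minimal layer protocol: forward/backward plus (param, grad) pairs."""

    def params(self):
        return []

    def forward(self, x, train):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g, need_dx=True):  # pragma: no cover - interface
        raise NotImplementedError


class _Conv3(_Layer):
    """3x3x3 'same' convolution, one GEMM per kernel offset."""

    def __init__(self, cin, cout, rng):
        std = np.sqrt(2.0 / (cin * 27))
        self.W = rng.normal(0.0, std, (27, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train):
        B, X, Y, Z, C = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        F = self.W.shape[2]
        out = np.empty((B * X * Y * Z, F), dtype=np.float32)
        out[:] = self.b
        for o, (di, dj, dk) in enumerate(_OFFSETS3):
            xs = xp[:, di:di + X, dj:dj + Y, dk:dk + Z, :].reshape(-1, C)
            out += xs @ self.W[o]
        if train:
            self._xp = xp
        return out.reshape(B, X, Y, Z, F)

    def backward(self, g, need_dx=True):
        xp = self._xp
        B = xp.shape[0]
        X, Y, Z = xp.shape[1] - 2, xp.shape[2] - 2, xp.shape[3] - 2
        C = xp.shape[4]
        gf = np.ascontiguousarray(g, dtype=np.float32).reshape(-1, self.W.shape[2])
        self.db[:] = gf.sum(axis=0)
        dxp = np.zeros_like(xp) if need_dx else None
        for o, (di, dj, dk) in enumerate(_OFFSETS3):
            xs = xp[:, di:di + X, dj:dj + Y, dk:dk + Z, :].reshape(-1, C)
            self.dW[o] = xs.T @ gf
            if need_dx:
                dxp[:, di:di + X, dj:dj + Y, dk:dk + Z, :] += \
                    (gf @ self.W[o].T).reshape(B, X, Y, Z, C)
        self._xp = None
        if need_dx:
            return dxp[:, 1:-1, 1:-1, 1:-1, :]
        return None


class _Conv1(_Layer):
    """1x1x1 convolution head."""

    def __init__(self, cin, cout, rng):
        std = np.sqrt(2.0 / cin)
        self.W = rng.normal(0.0, std, (cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train):
        if train:
            self._x = x
        out = x.reshape(-1, x.shape[-1]) @ self.W + self.b
        return out.reshape(x.shape[:-1] + (self.W.shape[1],))

    def backward(self, g, need_dx=True):
        gf = g.reshape(-1, g.shape[-1]).astype(np.float32)
        xf = self._x.reshape(-1, self._x.shape[-1])
        self.dW[:] = xf.T @ gf
        self.db[:] = gf.sum(axis=0)
        self._x = None
        if need_dx:
            return (gf @ self.W.T).reshape(g.shape[:-1] + (self.W.shape[0],))
        return None


class _BatchNorm(_Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train):
        if train:
            ax = (0, 1, 2, 3)
            mu = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv.astype(np.float32))
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, g, need_dx=True):
        xhat, inv = self._cache
        self._cache = None
        n = float(np.prod(g.shape[:-1]))
        ax = (0, 1, 2, 3)
        self.dgamma[:] = (g * xhat).sum(axis=ax)
        self.dbeta[:] = g.sum(axis=ax)
        if not need_dx:
            return None
        dxhat = g * self.gamma
        dx = (dxhat - dxhat.mean(axis=ax)
              - xhat * (dxhat * xhat).mean(axis=ax)) * inv
        del xhat
        return dx.astype(np.float32)


class _ReLU(_Layer):
    def forward(self, x, train):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, g, need_dx=True):
        g = g * self._mask
        self._mask = None
        return g


class _MaxPool2(_Layer):
    def forward(self, x, train):
        B, X, Y, Z, C = x.shape
        xr = x.reshape(B, X // 2, 2, Y // 2, 2, Z // 2, 2, C)
        xr = xr.transpose(0, 1, 3, 5, 2, 4, 6, 7).reshape(
            B, X // 2, Y // 2, Z // 2, 8, C)
        idx = xr.argmax(axis=4)
        out = np.take_along_axis(xr, idx[:, :, :, :, None, :], axis=4)[:, :, :, :, 0, :]
        if train:
            self._idx = idx
            self._in_shape = (B, X, Y, Z, C)
        return out

    def backward(self, g, need_dx=True):
        B, X, Y, Z, C = self._in_shape
        g8 = np.zeros((B, X // 2, Y // 2, Z // 2, 8, C), dtype=np.float32)
        np.put_along_axis(g8, self._idx[:, :, :, :, None, :],
                          g[:, :, :, :, None, :], axis=4)
        self._idx = None
        g8 = g8.reshape(B, X // 2, Y // 2, Z // 2, 2, 2, 2, C)
        g8 = g8.transpose(0, 1, 4, 2, 5, 3, 6, 7)
        return np.ascontiguousarray(g8.reshape(B, X, Y, Z, C))


class _TConv2(_Layer):
    """Transposed convolution, kernel 2x2x2, stride 2 (exact upsampling)."""

    def __init__(self, cin, cout, rng):
        std = np.sqrt(2.0 / cin)
        self.W = rng.normal(0.0, std, (8, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train):
        B, X, Y, Z, C = x.shape
        F = self.W.shape[2]
        out = np.empty((B, 2 * X, 2 * Y, 2 * Z, F), dtype=np.float32)
        xf = x.reshape(-1, C)
        for o, (di, dj, dk) in enumerate(_OFFSETS2):
            out[:, di::2, dj::2, dk::2, :] = (xf @ self.W[o]).reshape(B, X, Y, Z, F)
        out += self.b
        if train:
            self._x = x
        return out

    def backward(self, g, need_dx=True):
        x = self._x
        self._x = None
        B, X, Y, Z, C = x.shape
        F = self.W.shape[2]
        xf = x.reshape(-1, C)
        self.db[:] = g.sum(axis=(0, 1, 2, 3))
        dxf = np.zeros_like(xf) if need_dx else None
        for o, (di, dj, dk) in enumerate(_OFFSETS2):
            go = np.ascontiguousarray(g[:, di::2, dj::2, dk::2, :]).reshape(-1, F)
            self.dW[o] = xf.T @ go
            if need_dx:
                dxf += go @ self.W[o].T
        if need_dx:
            return dxf.reshape(B, X, Y, Z, C)
        return None


def _conv_block(cin, cout, rng):
    return [_BatchNorm(cin), _Conv3(cin, cout, rng), _ReLU()]


# ---------------------------------------------------------------------------
# the U-Net
# ---------------------------------------------------------------------------

class UNet3D:
    """Encoder-decoder with skip connections; see module docstring."""

    def __init__(self, cfg: UNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = [cfg.base_channels * 2 ** l for l in range(cfg.levels)]
        self.enc = []
        cin = cfg.in_channels
        for l in range(cfg.levels):
            self.enc.append(_conv_block(cin, ch[l], rng) + _conv_block(ch[l], ch[l], rng))
            cin = ch[l]
        self.pools = [_MaxPool2() for _ in range(cfg.levels - 1)]
        self.ups = []
        self.dec = []
        for l in range(cfg.levels - 2, -1, -1):
            self.ups.append(_TConv2(ch[l + 1], ch[l], rng))
            self.dec.append(_conv_block(2 * ch[l], ch[l], rng)
                            + _conv_block(ch[l], ch[l], rng))
        self.head = _Conv1(ch[0], cfg.out_classes, rng)

    # -- plumbing ---------------------------------------------------------
    def _all_layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.pools
        for up, blk in zip(self.ups, self.dec):
            yield up
            yield from blk
        yield self.head

    def params(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def state_dict(self):
        state = {}
        for i, layer in enumerate(self._all_layers()):
            for j, (p, _) in enumerate(layer.params()):
                state[f"p_{i}_{j}"] = p
            if isinstance(layer, _BatchNorm):
                state[f"rm_{i}"] = layer.running_mean
                state[f"rv_{i}"] = layer.running_var
        return state

    def load_state_dict(self, state):
        for i, layer in enumerate(self._all_layers()):
            for j, (p, _) in enumerate(layer.params()):
                p[...] = state[f"p_{i}_{j}"]
            if isinstance(layer, _BatchNorm):
                layer.running_mean[...] = state[f"rm_{i}"]
                layer.running_var[...] = state[f"rv_{i}"]

    # -- forward / backward ------------------------------------------------
    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 5 or x.shape[-1] != self.cfg.in_channels:
            raise ValueError(
                f"expected input (B, X, Y, Z, {self.cfg.in_channels}), got {x.shape}")
        self.cfg.check_shape(x.shape[1:4])
        skips = []
        for l in range(self.cfg.levels):
            for layer in self.enc[l]:
                x = layer.forward(x, train)
            if l < self.cfg.levels - 1:
                skips.append(x)
                x = self.pools[l].forward(x, train)
        self._skip_channels = []
        for up, blk in zip(self.ups, self.dec):
            x = up.forward(x, train)
            skip = skips.pop()
            self._skip_channels.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            for layer in blk:
                x = layer.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits):
        g = self.head.backward(dlogits)
        skip_grads = []
        # decoder stages in reverse order of execution
        for stage in range(len(self.dec) - 1, -1, -1):
            blk = self.dec[stage]
            for layer in reversed(blk):
                g = layer.backward(g)
            cskip = self._skip_channels[stage]
            g_skip, g_up = g[..., :cskip], g[..., cskip:]
            skip_grads.append(np.ascontiguousarray(g_skip))
            g = self.ups[stage].backward(np.ascontiguousarray(g_up))
        for l in range(self.cfg.levels - 1, -1, -1):
            if l < self.cfg.levels - 1:
                g = self.pools[l].backward(g)
                g = g + skip_grads[l]
            first = (l == 0)
            blk = self.enc[l]
            for pos, layer in enumerate(reversed(blk)):
                need_dx = not (first and pos == len(blk) - 1)
                g = layer.backward(g, need_dx=need_dx)
        return None

    def predict_proba(self, x):
        return softmax(self.forward(x, train=False))


def build_unet(cfg: UNetConfig) -> UNet3D:
    """Deterministically initialized, untrained model."""
    return UNet3D(cfg)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _one_hot(t: np.ndarray, k: int) -> np.ndarray:
    t = np.asarray(t)
    if t.ndim and t.shape[-1] == k and not np.issubdtype(t.dtype, np.integer):
        return t
    if np.issubdtype(t.dtype, np.integer) or t.ndim < 1:
        return np.eye(k, dtype=np.float32)[t]
    return t


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def loss_ce(p: np.ndarray, t: np.ndarray) -> float:
    """Cross entropy: mean over voxels of -log p at the true class.

    ``p`` is a probability field (..., K); ``t`` is either integer labels
    (...) or one-hot (..., K).  Probabilities are clipped at 1e-7.
    """
    p = np.asarray(p, dtype=np.float64)
    t = _one_hot(t, p.shape[-1]).astype(np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs t {t.shape}")
    return float(-(t * np.log(np.clip(p, CE_EPS, 1.0))).sum(axis=-1).mean())


def _gdl_terms(p, t, weight_power):
    k = p.shape[-1]
    pf = p.reshape(-1, k).astype(np.float64)
    rf = _one_hot(t, k).reshape(-1, k).astype(np.float64)
    r_sum = rf.sum(axis=0)
    with np.errstate(divide="ignore"):
        w = np.where(r_sum > 0, 1.0 / np.maximum(r_sum, 1e-300) ** weight_power, 0.0)
    inter = (rf * pf).sum(axis=0)
    union = (rf + pf).sum(axis=0)
    num = (w * inter).sum()
    den = (w * union).sum()
    return pf, rf, w, num, den


def loss_gdl(p: np.ndarray, t: np.ndarray, weight_power: int = 2) -> float:
    """Generalized Dice loss with inverse-volume class weights.

    ``weight_power=2`` uses w_l = 1/(sum_n r_ln)^2 (the canonical
    definition); ``weight_power=1`` uses w_l = 1/(sum_n r_ln).  Classes
    absent from the target are dropped.  Result clipped to [0, 1].
    """
    p = np.asarray(p, dtype=np.float64)
    if _one_hot(t, p.shape[-1]).shape != p.shape:
        raise ValueError("shape mismatch between prediction and target")
    _, _, _, num, den = _gdl_terms(p, t, weight_power)
    val = 1.0 - 2.0 * (num + GDL_EPS) / (den + GDL_EPS)
    return float(min(max(val, 0.0), 1.0))


def _loss_and_dlogits(logits, t_int, loss_kind, weight_power,
                      class_weights=None):
    """Loss value and gradient with respect to the logits.

    ``class_weights`` (CE only) scales each voxel's contribution by the
    weight of its true class.
    """
    p = softmax(logits.astype(np.float64))
    k = p.shape[-1]
    t = np.eye(k)[t_int]
    n = float(np.prod(t_int.shape))
    if loss_kind == "ce":
        nll = -(t * np.log(np.clip(p, CE_EPS, 1.0))).sum(axis=-1)
        if class_weights is None:
            val = float(nll.mean())
            dz = (p - t) / n
        else:
            wv = np.asarray(class_weights, dtype=np.float64)[t_int]
            val = float((wv * nll).mean())
            dz = wv[..., None] * (p - t) / n
    else:
        pf, rf, w, num, den = _gdl_terms(p, t, weight_power)
        val = 1.0 - 2.0 * (num + GDL_EPS) / (den + GDL_EPS)
        dnum = w[None, :] * rf
        dden = np.broadcast_to(w[None, :], pf.shape)
        dp = -2.0 * (dnum * (den + GDL_EPS) - (num + GDL_EPS) * dden) \
            / (den + GDL_EPS) ** 2
        dp = dp.reshape(p.shape)
        dz = p * (dp - (p * dp).sum(axis=-1, keepdims=True))
        val = float(min(max(val, 0.0), 1.0))
    return val, dz.astype(np.float32)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _as_rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def augment_flip(patch: np.ndarray, labels: Optional[np.ndarray], seed):
    """Mirror patch (and labels) about the midline with probability 0.5.

    The right-left axis is the first grid axis, so the flip reverses
    axis 0; per-class voxel counts are unchanged.
    """
    rng = _as_rng(seed)
    if rng.random() < 0.5:
        patch = patch[::-1].copy()
        labels = labels[::-1].copy() if labels is not None else None
    return patch, labels


def augment_noise(patch: np.ndarray, sd_max: float, seed) -> np.ndarray:
    """Add Gaussian noise with sd drawn uniformly from [0, sd_max]."""
    if sd_max < 0:
        raise ValueError("sd_max must be >= 0")
    rng = _as_rng(seed)
    if sd_max == 0:
        return patch
    sd = rng.uniform(0.0, sd_max)
    return patch + rng.normal(0.0, sd, patch.shape).astype(patch.dtype)


def augment_clahe(patch: np.ndarray, clip_limit: float = 0.01,
                  tiles: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, applied as a
    stack of 2-D equalizations along the right-left axis.  The patch is
    min-max rescaled to [0, 1] first; a constant patch is returned
    unchanged (rescaled histograms are degenerate)."""
    from skimage import exposure

    patch = np.asarray(patch, dtype=np.float64)
    lo, hi = patch.min(), patch.max()
    if hi - lo < 1e-12:
        return patch
    scaled = (patch - lo) / (hi - lo)
    out = np.empty_like(scaled)
    ks = tuple(max(s // tiles, 2) for s in scaled.shape[1:])
    for i in range(scaled.shape[0]):
        out[i] = exposure.equalize_adapthist(scaled[i], kernel_size=ks,
                                             clip_limit=clip_limit)
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainingSample:
    """One training patch: raw image, optional auxiliary channel (the
    pre-label map for FCNN_labels), integer targets, padding mask."""

    image: np.ndarray
    labels: np.ndarray
    aux: Optional[np.ndarray] = None
    pad_mask: Optional[np.ndarray] = None


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self, params):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (p, g) in enumerate(params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def _prepare_sample(s: TrainingSample, cfg: TrainConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    img = np.asarray(s.image, dtype=np.float32)
    lab = np.asarray(s.labels)
    aux = None if s.aux is None else np.asarray(s.aux, dtype=np.float32)
    pad = s.pad_mask if s.pad_mask is not None else np.zeros(img.shape, dtype=bool)
    if cfg.augment_flip:
        stacked = img if aux is None else np.stack([img, aux], axis=-1)
        joint = np.concatenate(
            [stacked[..., None] if stacked.ndim == 3 else stacked,
             lab[..., None], pad[..., None]], axis=-1)
        joint, _ = augment_flip(joint, None, rng)
        nimg = 1 if aux is None else 2
        img = joint[..., 0]
        aux = joint[..., 1] if aux is not None else None
        lab = joint[..., nimg].astype(lab.dtype)
        pad = joint[..., nimg + 1].astype(bool)
    if cfg.augment_clahe:
        img = augment_clahe(img, cfg.clahe_clip, cfg.clahe_tiles).astype(np.float32)
    z = zscore_array(img, pad)
    if cfg.augment_noise and cfg.noise_sd_max > 0:
        z = augment_noise(z, cfg.noise_sd_max, rng)
    chans = [z] if aux is None else [z, aux]
    return np.stack(chans, axis=-1).astype(np.float32), lab.astype(np.int64)


def train(model: UNet3D, dataset: Sequence[TrainingSample], cfg: TrainConfig,
          val_dataset: Optional[Sequence[TrainingSample]] = None,
          max_steps: Optional[int] = None,
          val_every_steps: Optional[int] = None):
    """Train with Adam; returns ``(model, history)``.

    ``history`` is the per-epoch mean training loss (plus validation loss
    when a validation set is supplied; early stopping restores the best
    validation parameters after ``early_stop_patience`` flat epochs).
    ``max_steps`` caps the total number of optimizer steps regardless of
    epochs.  ``val_every_steps`` switches validation from per-epoch to a
    step interval (the pre-training state is then also a restore
    candidate), which protects short fine-tuning phases whose loss can
    deteriorate within a fraction of an epoch.  Fixed ``cfg.seed`` makes
    the run bit-reproducible.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    k = model.cfg.out_classes
    counts = np.zeros(k, dtype=np.float64)
    for s in dataset:
        counts += np.bincount(np.asarray(s.labels).ravel(), minlength=k)[:k]
    if cfg.loss == "ce" and cfg.head_prior_init:
        # initialize the head bias at the log class prior of the training
        # set: the network starts at the base-rate prediction instead of
        # spending its first steps learning how rare the foreground is.
        # (Not applied under generalized Dice: its softmax gradient for a
        # class scales with that class's probability, so a rare-class
        # prior would stall rare-class learning.)
        prior = (counts + 1.0) / (counts.sum() + k)
        model.head.b[:] = np.log(prior).astype(np.float32)
    class_weights = None
    if cfg.loss == "ce" and cfg.class_weight_power > 0:
        # median-frequency balancing: rare classes get gradient from the
        # first step instead of waiting for a slow emergence knee
        freq = counts / max(counts.sum(), 1.0)
        with np.errstate(divide="ignore"):
            w = np.where(freq > 0,
                         (np.median(freq[freq > 0]) / np.maximum(freq, 1e-12))
                         ** cfg.class_weight_power, 0.0)
        class_weights = w
    opt = _Adam(model.params(), cfg.learning_rate)
    eval_cfg = TrainConfig(**{**asdict(cfg), "augment_flip": False,
                              "augment_noise": False, "augment_clahe": False})
    eval_rng = np.random.default_rng(cfg.seed)

    def val_loss() -> float:
        """Validation score to minimize.

        ``loss`` evaluates the configured training loss; ``macro_dice``
        evaluates 1 − mean per-class Dice of the arg-max labeling — the
        study's evaluation metric — which is the appropriate selection
        criterion when the training loss's optimum is degenerate for
        very rare classes.
        """
        if cfg.val_metric == "macro_dice":
            k = model.cfg.out_classes
            inter = np.zeros(k)
            sizes = np.zeros(k)
            for s in val_dataset:
                x, t = _prepare_sample(s, eval_cfg, eval_rng)
                pred = model.predict_proba(x[None])[0].argmax(axis=-1)
                for c in range(k):
                    inter[c] += np.sum((pred == c) & (t == c))
                    sizes[c] += np.sum(pred == c) + np.sum(t == c)
            present = sizes > 0
            dice = 2 * inter[present] / sizes[present]
            return 1.0 - float(dice.mean())
        vlosses = []
        for s in val_dataset:
            x, t = _prepare_sample(s, eval_cfg, eval_rng)
            p = model.predict_proba(x[None])
            vlosses.append(loss_ce(p[0], t) if cfg.loss == "ce"
                           else loss_gdl(p[0], t, cfg.weight_power))
        return float(np.mean(vlosses))

    history = []
    best_val, best_state, patience = np.inf, None, 0

    def check_val(entry=None):
        nonlocal best_val, best_state, patience
        v = val_loss()
        if entry is not None:
            entry["val_loss"] = v
        if v < best_val - 1e-9:
            best_val = v
            best_state = {k: a.copy() for k, a in model.state_dict().items()}
            patience = 0
        else:
            patience += 1
        return v

    if val_dataset and val_every_steps:
        check_val()   # the untrained/warm-started state is a candidate
    steps_done = 0
    stop = False
    for epoch in range(cfg.epochs):
        if stop or (max_steps is not None and steps_done >= max_steps):
            break
        order = rng.permutation(len(dataset)) if cfg.shuffle else np.arange(len(dataset))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            if max_steps is not None and steps_done >= max_steps:
                break
            idx = order[start:start + cfg.batch_size]
            xs, ts = zip(*(_prepare_sample(dataset[i], cfg, rng) for i in idx))
            x = np.stack(xs)
            t = np.stack(ts)
            logits = model.forward(x, train=True)
            val, dz = _loss_and_dlogits(logits, t, cfg.loss, cfg.weight_power,
                                        class_weights)
            model.backward(dz)
            opt.step(model.params())
            losses.append(val)
            steps_done += 1
            if (val_dataset and val_every_steps
                    and steps_done % val_every_steps == 0):
                check_val()
                if patience >= cfg.early_stop_patience:
                    stop = True
                    break
        if not losses:
            break
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_dataset and not val_every_steps:
            check_val(entry)
            if patience >= cfg.early_stop_patience:
                stop = True
        history.append(entry)
        log.info("epoch %d: %s", epoch, entry)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _predict_field(model, channels, region_mask, overlap=0.5, dilate=8):
    """Stitched class-probability field over a full grid.

    ``channels`` is a list of full-grid arrays; channel 0 is z-scored per
    patch, further channels are passed through untouched.
    """
    origins = inference_patch_origins(region_mask, PATCH_SHAPE, overlap, dilate)
    pieces = []
    for origin in origins:
        center = tuple(o + s // 2 for o, s in zip(origin, PATCH_SHAPE))
        parts = []
        patch_origin = origin
        for ci, chan in enumerate(channels):
            p = extract_patch(chan, center)
            patch_origin = p.origin
            parts.append(zscore_patch(p).data if ci == 0 else
                         p.data.astype(np.float32))
        x = np.stack(parts, axis=-1)[None]
        probs = model.predict_proba(x)[0]
        pieces.append((probs, patch_origin))
    return stitch_predictions(pieces, region_mask.shape)


def predict_mask(model: UNet3D, v: Volume3D, atlas) -> LabelMap:
    """Binary peri-sinus mask from the first-stage network.

    Patches follow the atlas-guided sliding layout; stitched softmax
    probabilities are arg-maxed into {0, 1}.
    """
    if model.cfg.out_classes != 2 or model.cfg.in_channels != 1:
        raise ValueError("predict_mask expects a 2-class, 1-channel model")
    if tuple(atlas.shape) != tuple(v.shape):
        raise ValueError("atlas grid does not match the volume")
    field = _predict_field(model, [np.asarray(v.data, dtype=np.float32)],
                           np.asarray(atlas.data) > 0)
    mask = field.argmax(axis=-1).astype(np.int16)
    return LabelMap(mask, v.spacing, v.affine.copy(), v.space_tag)


def predict_labels(model: UNet3D, v: Volume3D, prelabel: LabelMap) -> LabelMap:
    """Four-class labeling from the second-stage network.

    Inputs are the z-scored image and the pre-label map (codes 0/1/2) as
    a second channel; the final label is the per-voxel argmax of the
    stitched probabilities, ties broken toward the lowest class code.
    """
    if model.cfg.out_classes != 4 or model.cfg.in_channels != 2:
        raise ValueError("predict_labels expects a 4-class, 2-channel model")
    if not prelabel.same_grid(v):
        raise ValueError("pre-label map and volume are on different grids")
    field = _predict_field(
        model,
        [np.asarray(v.data, dtype=np.float32),
         np.asarray(prelabel.data, dtype=np.float32)],
        np.asarray(prelabel.data) > 0)
    lab = field.argmax(axis=-1).astype(np.int16)
    return LabelMap(lab, v.spacing, v.affine.copy(), v.space_tag)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model: UNet3D, path, train_config: Optional[TrainConfig] = None) -> None:
    """Checkpoint: parameters plus embedded config/seed."""
    meta = {"unet": asdict(model.cfg)}
    if train_config is not None:
        meta["train"] = asdict(train_config)
    np.savez(path, __meta__=json.dumps(meta), **model.state_dict())


def load_model(path) -> UNet3D:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        model = UNet3D(UNetConfig(**meta["unet"]))
        model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
    return model
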