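"""Lightweight convolutional encoder-decoder for epithelium segmentation.

A small 3-level U-style network (two 2x2 max-pool downsamplings, nearest
upsampling, skip connections by channel concatenation) implemented
directly on numpy with hand-written backpropagation, trained with Adam on
a combined binary-cross-entropy + soft-Dice loss.  It is sized for the
synthetic B-scan phantoms of this package: single-channel inputs whose
height and width are multiples of 4, 8/16/32 feature channels.

The inference path thresholds the per-pixel probability map (default 0.6),
keeps the largest connected band, and extracts per-column boundaries, so
its output is interchangeable with the classical segmenter's.

Training here is CPU-bound and deliberately small-scale; it exists so the
whole segmentation path can be exercised end to end without any external
weights.  Checkpoints are .npz archives with a JSON metadata entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label

from .epithelium import EpitheliumSegmentation, band_mask_from_boundaries, evaluate_segmentation

__all__ = [
    "EncoderDecoder",
    "train_network",
    "segment_epithelium_network",
    "predict_proba",
]

DEFAULT_THRESHOLD = 0.6


# ---------------------------------------------------------------- layers

class _Conv:
    """3x3 (or 1x1) same-padding convolution on NHWC tensors."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * cin))  # He init
        self.W = (rng.standard_normal((k, k, cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xpad = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xpad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._xpad = xpad
        n, h, w, _ = x.shape
        y = np.broadcast_to(self.b, (n, h, w, self.W.shape[-1])).copy()
        for i in range(k):
            for j in range(k):
                y += xpad[:, i:i + h, j:j + w, :] @ self.W[i, j]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xpad = self._xpad
        n, h, w, _ = dy.shape
        self.db[:] = dy.sum(axis=(0, 1, 2))
        dxpad = np.zeros_like(xpad)
        for i in range(k):
            for j in range(k):
                xs = xpad[:, i:i + h, j:j + w, :]
                self.dW[i, j] = np.tensordot(xs, dy, axes=([0, 1, 2], [0, 1, 2]))
                dxpad[:, i:i + h, j:j + w, :] += dy @ self.W[i, j].T
        self._xpad = None
        return dxpad[:, p:p + h, p:p + w, :] if p else dxpad

    def params(self):
        return [("W", self), ("b", self)]


def _relu_fwd(x):
    return np.maximum(x, 0.0), x > 0


def _pool2_fwd(x):
    n, h, w, c = x.shape
    v = x.reshape(n, h // 2, 2, w // 2, 2, c)
    y = v.max(axis=(2, 4))
    mask = v == y[:, :, None, :, None, :]
    return y, (mask, x.shape)


def _pool2_bwd(dy, cache):
    mask, shape = cache
    n, h, w, c = shape
    dv = mask * dy[:, :, None, :, None, :]
    return dv.reshape(n, h, w, c)


def _up2_fwd(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _up2_bwd(dy):
    n, h, w, c = dy.shape
    return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


# ---------------------------------------------------------------- network

@dataclass
class EncoderDecoder:
    """3-level encoder-decoder with skip connections (numpy backend)."""

    base_channels: int = 8
    seed: int = 0
    trained: bool = False
    history: list = field(default_factory=list)

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        c = self.base_channels
        self.layers = {
            "e1a": _Conv(1, c, 3, rng), "e1b": _Conv(c, c, 3, rng),
            "e2a": _Conv(c, 2 * c, 3, rng), "e2b": _Conv(2 * c, 2 * c, 3, rng),
            "bna": _Conv(2 * c, 4 * c, 3, rng), "bnb": _Conv(4 * c, 4 * c, 3, rng),
            "u2": _Conv(4 * c, 2 * c, 3, rng),
            "d2a": _Conv(4 * c, 2 * c, 3, rng), "d2b": _Conv(2 * c, 2 * c, 3, rng),
            "u1": _Conv(2 * c, c, 3, rng),
            "d1a": _Conv(2 * c, c, 3, rng), "d1b": _Conv(c, c, 3, rng),
            "out": _Conv(c, 1, 1, rng),
        }

    # -- forward -------------------------------------------------------
    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Logits of a batch (N, H, W) or (N, H, W, 1); H, W % 4 == 0."""
        if x.ndim == 3:
            x = x[..., None]
        x = x.astype(np.float32)
        if x.shape[1] % 4 or x.shape[2] % 4:
            raise ValueError("input height and width must be multiples of 4")
        L = self.layers
        cache = {}

        def conv_relu(name, t):
            z = L[name].forward(t)
            a, m = _relu_fwd(z)
            cache[name] = m
            return a

        s1 = conv_relu("e1b", conv_relu("e1a", x))
        p1, cache["pool1"] = _pool2_fwd(s1)
        s2 = conv_relu("e2b", conv_relu("e2a", p1))
        p2, cache["pool2"] = _pool2_fwd(s2)
        bn = conv_relu("bnb", conv_relu("bna", p2))

        u2 = conv_relu("u2", _up2_fwd(bn))
        c2 = np.concatenate([u2, s2], axis=-1)
        d2 = conv_relu("d2b", conv_relu("d2a", c2))
        u1 = conv_relu("u1", _up2_fwd(d2))
        c1 = np.concatenate([u1, s1], axis=-1)
        d1 = conv_relu("d1b", conv_relu("d1a", c1))
        logits = L["out"].forward(d1)[..., 0]
        if keep_cache:
            self._cache = cache
            self._ch = self.base_channels
        return logits

    # -- backward ------------------------------------------------------
    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logits); fills layer gradients."""
        L, cache, c = self.layers, self._cache, self._ch

        def conv_bwd(name, d):
            return L[name].backward(d * cache[name])

        d = L["out"].backward(dlogits[..., None])
        d = conv_bwd("d1a", conv_bwd("d1b", d))
        du1, ds1 = d[..., :c], d[..., c:]
        d = _up2_bwd(conv_bwd("u1", du1))
        d = conv_bwd("d2a", conv_bwd("d2b", d))
        du2, ds2 = d[..., :2 * c], d[..., 2 * c:]
        d = _up2_bwd(conv_bwd("u2", du2))
        d = conv_bwd("bna", conv_bwd("bnb", d))
        d = _pool2_bwd(d, cache["pool2"]) + ds2
        d = conv_bwd("e2a", conv_bwd("e2b", d))
        d = _pool2_bwd(d, cache["pool1"]) + ds1
        conv_bwd("e1a", conv_bwd("e1b", d))
        self._cache = None

    # -- parameter access / persistence --------------------------------
    def state_dict(self) -> dict:
        out = {}
        for name, layer in self.layers.items():
            out[f"{name}.W"] = layer.W.copy()
            out[f"{name}.b"] = layer.b.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        for name, layer in self.layers.items():
            layer.W[:] = state[f"{name}.W"]
            layer.b[:] = state[f"{name}.b"]

    def save(self, path) -> None:
        meta = json.dumps({
            "base_channels": self.base_channels, "seed": self.seed,
            "trained": self.trained, "history": self.history,
        })
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "EncoderDecoder":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(base_channels=meta["base_channels"], seed=meta["seed"])
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        model.trained = meta["trained"]
        model.history = meta["history"]
        return model


# ---------------------------------------------------------------- loss

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def _bce_dice_loss(logits: np.ndarray, targets: np.ndarray):
    """Combined BCE + soft-Dice loss and its gradient w.r.t. the logits."""
    p = _sigmoid(logits)
    t = targets.astype(np.float32)
    eps = 1e-7
    n = p.size
    bce = -np.mean(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps))
    dbce_dp = (-(t / (p + eps)) + (1 - t) / (1 - p + eps)) / n

    inter = float((p * t).sum())
    total = float(p.sum() + t.sum())
    dice = (2 * inter + 1.0) / (total + 1.0)
    ddice_dp = (2 * t * (total + 1.0) - (2 * inter + 1.0)) / (total + 1.0) ** 2

    loss = bce + (1.0 - dice)
    dloss_dp = dbce_dp - ddice_dp
    dlogits = dloss_dp * p * (1 - p)
    return float(loss), dlogits.astype(np.float32)


class _Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = {}
        self.layers = layers
        for name, layer in layers.items():
            for attr in ("W", "b"):
                arr = getattr(layer, attr)
                self.state[(name, attr)] = (np.zeros_like(arr), np.zeros_like(arr))

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for name, layer in self.layers.items():
            for attr in ("W", "b"):
                g = getattr(layer, "d" + attr)
                m, v = self.state[(name, attr)]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                getattr(layer, attr)[...] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------- API

def predict_proba(model: EncoderDecoder, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Per-pixel probability maps for a stack of (N, H, W) images."""
    outs = []
    for i in range(0, len(images), batch_size):
        outs.append(_sigmoid(model.forward(images[i:i + batch_size])))
    return np.concatenate(outs, axis=0)


def _dice_of_stack(model, images, masks, threshold):
    probs = predict_proba(model, images)
    scores = [
        evaluate_segmentation(probs[i] >= threshold, masks[i]).dice
        for i in range(len(images))
    ]
    return float(np.mean(scores))


def train_network(
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    epochs: int = 12,
    seed: int = 0,
    lr: float = 2e-3,
    batch_size: int = 8,
    base_channels: int = 8,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[EncoderDecoder, list]:
    """Train the encoder-decoder on (B-scan, mask) pairs.

    Parameters
    ----------
    train, val
        Tuples ``(images, masks)`` with shapes (N, H, W); images in [0, 1],
        masks boolean.  At least 50 training pairs are required.
    epochs, seed, lr, batch_size, base_channels
        Optimization settings; identical seeds give identical histories.
    threshold
        Probability threshold used for the validation Dice in the history.

    Returns
    -------
    (model, history)
        The model restored to its best-validation-Dice checkpoint, and a
        per-epoch list of ``{"epoch", "train_loss", "val_dice"}`` records.
    """
    x_tr, y_tr = np.asarray(train[0], dtype=np.float32), np.asarray(train[1])
    x_va, y_va = np.asarray(val[0], dtype=np.float32), np.asarray(val[1])
    if len(x_tr) == 0:
        raise ValueError("empty training set")
    if len(x_tr) < 50:
        raise ValueError(f"need >= 50 training pairs, got {len(x_tr)}")
    if x_tr.shape != y_tr.shape or x_va.shape != y_va.shape:
        raise ValueError("image and mask stacks must have identical shapes")

    rng = np.random.default_rng(seed)
    model = EncoderDecoder(base_channels=base_channels, seed=seed)
    opt = _Adam(model.layers, lr=lr)
    best = (-1.0, model.state_dict())
    history = []
    n = len(x_tr)
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            logits = model.forward(x_tr[idx], keep_cache=True)
            loss, dlogits = _bce_dice_loss(logits, y_tr[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_dice = _dice_of_stack(model, x_va, y_va, threshold)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_dice": val_dice})
        if val_dice > best[0]:
            best = (val_dice, model.state_dict())
    model.load_state_dict(best[1])
    model.trained = True
    model.history = history
    return model, history


def segment_epithelium_network(
    bscan: np.ndarray,
    model: EncoderDecoder,
    threshold: float = DEFAULT_THRESHOLD,
) -> EpitheliumSegmentation:
    """Segment one B-scan (z, x) with a trained encoder-decoder.

    The probability map is thresholded (default 0.6), the largest
    connected band is kept, and per-column upper/lower boundaries are
    extracted from it; the returned mask is filled between the boundaries.
    """
    if not model.trained:
        raise ValueError("model is untrained; train it first with train_network()")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    img = np.asarray(bscan, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("B-scan must be a 2-D (z, x) image")
    peak = img.max()
    if peak > 0:
        img = img / peak
    nz, nx = img.shape
    pz = (-nz) % 4
    px = (-nx) % 4
    padded = np.pad(img, ((0, pz), (0, px)), mode="edge")
    prob = _sigmoid(model.forward(padded[None]))[0][:nz, :nx]

    raw = prob >= threshold
    if raw.any():
        labels = label(raw)
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        band = labels == largest
    else:
        band = raw
    valid = band.any(axis=0)
    upper = np.zeros(nx, dtype=int)
    lower = np.zeros(nx, dtype=int)
    zidx = np.arange(nz)
    for x in np.flatnonzero(valid):
        col = zidx[band[:, x]]
        upper[x] = col[0]
        lower[x] = col[-1] + 1
    return EpitheliumSegmentation(
        mask=band_mask_from_boundaries(upper, lower, nz),
        upper_boundary=upper,
        lower_boundary=lower,
        valid=valid,
        method="network",
        probability_threshold=threshold,
    )
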