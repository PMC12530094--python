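"""From-scratch CNN classifiers for 36-channel polarimetric inputs.

Two small VGG-style binary classifiers operate on the 224 x 224 x 36 model
inputs: ``cnn`` stacks 3x3 convolutional blocks (Conv + BatchNorm + ReLU +
Dropout 0.2) with max pooling and a 512 -> 256 -> 1 fully connected head;
``cnn_2`` replaces every pooling stage with a stride-2 convolutional block
and the fully connected head with 1x1 convolutions. Training follows the
published protocol: AdamW, binary cross-entropy, batch size 16, up to 200
epochs, ReduceLROnPlateau scheduling and early stopping on validation loss.

Everything — forward, backward, the optimizer, the schedulers — is
implemented in numpy so the module carries no deep-learning framework
dependency; widths, depth and input size are configurable so that training
can be exercised at desk scale.

Also provided: the first-layer channel-inflation contract for adapting
3-channel pretrained weights to 36 channels (first 3 channels copied
bit-exact, the remainder He-initialized), and label-preserving joint-channel
augmentations (rotation, CLAHE, blur).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .stats import ConfusionCounts, classification_metrics

__all__ = [
    "TrainConfig",
    "build_cnn",
    "Model",
    "train",
    "evaluate",
    "inflate_first_layer",
    "augment",
    "he_std",
]


def he_std(fan_in: int) -> float:
    """Standard deviation of the He normal initializer."""
    return float(np.sqrt(2.0 / fan_in))


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, train: bool, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError

    def manifest(self) -> dict:
        n = sum(int(p.size) for p in self.params.values())
        return {"type": type(self).__name__.lstrip("_"), "n_params": n}


class _Conv2D(_Layer):
    """k x k convolution via im2col; 'same' padding of k // 2."""

    def __init__(self, in_ch, out_ch, k=3, stride=1, rng=None):
        super().__init__()
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        std = he_std(in_ch * k * k)
        rng = rng or np.random.default_rng(0)
        self.params = {
            "w": rng.normal(0.0, std, size=(out_ch, in_ch, k, k)),
            "b": np.zeros(out_ch),
        }

    def forward(self, x, train, rng=None):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, ho, wo, k, k)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        w2 = self.params["w"].reshape(self.out_ch, -1)
        out = cols @ w2.T + self.params["b"]
        self._cache = (cols, x.shape, (ho, wo))
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, g):
        cols, xshape, (ho, wo) = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.k // 2
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        self.grads["w"] = (g2.T @ cols).reshape(self.params["w"].shape)
        self.grads["b"] = g2.sum(axis=0)
        dcols = (g2 @ self.params["w"].reshape(self.out_ch, -1))
        dcols = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[..., i, j]
        return dxp[:, :, p : p + h, p : p + w]

    def manifest(self):
        m = super().manifest()
        m.update(kernel=self.k, stride=self.stride, in_ch=self.in_ch, out_ch=self.out_ch)
        return m


class _BatchNorm2D(_Layer):
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(ch), "beta": np.zeros(ch)}
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)

    def forward(self, x, train, rng=None):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        self._cache = (xhat, inv, x.shape, train)
        return self.params["gamma"][:, None, None] * xhat + self.params["beta"][:, None, None]

    def backward(self, g):
        xhat, inv, shape, train = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.grads["gamma"] = (g * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = g.sum(axis=(0, 2, 3))
        gg = g * self.params["gamma"][:, None, None]
        if not train:
            return gg * inv[:, None, None]
        t1 = gg.sum(axis=(0, 2, 3)) / m
        t2 = (gg * xhat).sum(axis=(0, 2, 3)) / m
        return inv[:, None, None] * (gg - t1[:, None, None] - xhat * t2[:, None, None])


class _ReLU(_Layer):
    def forward(self, x, train, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class _Dropout(_Layer):
    def __init__(self, p=0.2):
        super().__init__()
        self.p = p

    def forward(self, x, train, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def manifest(self):
        m = super().manifest()
        m["p"] = self.p
        return m


class _MaxPool2D(_Layer):
    def __init__(self, k=2):
        super().__init__()
        self.k = k

    def forward(self, x, train, rng=None):
        n, c, h, w = x.shape
        k = self.k
        ho, wo = h // k, w // k
        xv = x[:, :, : ho * k, : wo * k].reshape(n, c, ho, k, wo, k)
        xv = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, k * k)
        self._arg = xv.argmax(axis=-1)
        self._xshape = x.shape
        return xv.max(axis=-1)

    def backward(self, g):
        n, c, h, w = self._xshape
        k = self.k
        ho, wo = h // k, w // k
        onehot = np.eye(k * k)[self._arg]  # (n, c, ho, wo, k*k)
        dv = (g[..., None] * onehot).reshape(n, c, ho, wo, k, k)
        dx = np.zeros((n, c, h, w))
        dx[:, :, : ho * k, : wo * k] = dv.transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ho * k, wo * k
        )
        return dx


class _GlobalAvgPool(_Layer):
    def forward(self, x, train, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        n, c, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None], self._shape) / (h * w)


class _Dense(_Layer):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        rng = rng or np.random.default_rng(0)
        self.params = {
            "w": rng.normal(0.0, he_std(n_in), size=(n_out, n_in)),
            "b": np.zeros(n_out),
        }

    def forward(self, x, train, rng=None):
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, g):
        self.grads["w"] = g.T @ self._x
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["w"]

    def manifest(self):
        m = super().manifest()
        m.update(n_in=self.n_in, n_out=self.n_out)
        return m


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                    np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))


def _bce_with_logits(z, y):
    """Stable mean binary cross-entropy and its gradient w.r.t. logits."""
    z = z.ravel()
    loss = float(np.mean(np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))))
    grad = ((_sigmoid(z) - y) / z.size).reshape(-1, 1)
    return loss, grad


@dataclass
class Model:
    """A sequential stack of layers producing one logit per sample."""

    layers: list
    variant: str
    seed: int
    _rng: np.random.Generator = field(default=None, repr=False)

    def __post_init__(self):
        if self._rng is None:
            self._rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7]))

    def forward(self, x, train: bool = False) -> np.ndarray:
        """Logits for input ``x`` of shape (N, C, H, W)."""
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=self._rng)
        self._final_shape = x.shape
        return x.reshape(len(x), -1).mean(axis=1)  # (N,) logit

    def backward(self, grad_logit):
        shape = self._final_shape
        per = int(np.prod(shape[1:]))
        g = np.asarray(grad_logit).reshape(-1, 1)
        g = np.broadcast_to(g / per, (shape[0], per)).reshape(shape)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def predict_proba(self, x) -> np.ndarray:
        return _sigmoid(self.forward(x, train=False))

    def loss_on_batch(self, x, y, train: bool = False) -> float:
        z = self.forward(x, train=train)
        return _bce_with_logits(z, np.asarray(y, float))[0]

    def parameters(self):
        for layer in self.layers:
            for name, p in layer.params.items():
                yield layer, name, p

    @property
    def n_params(self) -> int:
        return sum(p.size for _, _, p in self.parameters())

    def manifest(self) -> dict:
        return {
            "variant": self.variant,
            "seed": self.seed,
            "n_params": int(self.n_params),
            "layers": [layer.manifest() for layer in self.layers],
        }


def _conv_block(in_ch, out_ch, k, stride, dropout, batch_norm, rng):
    block = [_Conv2D(in_ch, out_ch, k=k, stride=stride, rng=rng)]
    if batch_norm:
        block.append(_BatchNorm2D(out_ch))
    block.append(_ReLU())
    if dropout > 0:
        block.append(_Dropout(dropout))
    return block


def build_cnn(
    variant: str = "cnn",
    in_channels: int = 36,
    widths: tuple = (128, 256, 512),
    head_width: int = 256,
    dropout: float = 0.2,
    batch_norm: bool = True,
    seed: int = 0,
) -> Model:
    """Build the ``cnn`` or ``cnn_2`` architecture.

    ``cnn``: [ConvBlock k3 + MaxPool] per stage, global average pooling,
    then fully connected widths[-1] -> head_width -> 1.
    ``cnn_2``: per stage a stride-1 ConvBlock followed by a stride-2
    ConvBlock (replacing pooling); the head is a 1x1 ConvBlock to
    ``head_width`` and a final 1x1 convolution to one logit channel,
    averaged spatially — no fully connected layers.
    """
    if variant not in ("cnn", "cnn_2"):
        raise ValueError(f"unknown variant {variant!r}")
    if not widths:
        raise ValueError("need at least one stage width")
    rng = np.random.default_rng(seed)
    layers: list = []
    prev = in_channels
    for w in widths:
        if variant == "cnn":
            layers += _conv_block(prev, w, 3, 1, dropout, batch_norm, rng)
            layers.append(_MaxPool2D(2))
        else:
            layers += _conv_block(prev, w, 3, 1, dropout, batch_norm, rng)
            layers += _conv_block(w, w, 3, 2, dropout, batch_norm, rng)
        prev = w
    if variant == "cnn":
        layers.append(_GlobalAvgPool())
        layers.append(_Dense(prev, head_width, rng=rng))
        layers.append(_ReLU())
        layers.append(_Dense(head_width, 1, rng=rng))
    else:
        layers += _conv_block(prev, head_width, 1, 1, dropout, batch_norm, rng)
        layers.append(_Conv2D(head_width, 1, k=1, stride=1, rng=rng))
        layers.append(_GlobalAvgPool())
    return Model(layers=layers, variant=variant, seed=seed)


# ---------------------------------------------------------------------------
# Optimizer, schedulers, training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Published training protocol; every field is overridable and logged."""

    batch_size: int = 16
    max_epochs: int = 200
    learning_rate: float = 0.01  # models trained from scratch
    weight_decay: float = 0.001
    plateau_factor: float = 0.1
    plateau_patience: int = 10
    early_stop_patience: int = 20
    min_improvement: float = 1e-6
    threshold: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


class _AdamW:
    def __init__(self, model, lr, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model, self.lr, self.wd = model, lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state = {}
        for i, (layer, name, p) in enumerate(model.parameters()):
            self.state[(i)] = (np.zeros_like(p), np.zeros_like(p))

    def step(self):
        self.t += 1
        for i, (layer, name, p) in enumerate(self.model.parameters()):
            g = layer.grads.get(name)
            if g is None:
                continue
            m, v = self.state[i]
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * (mh / (np.sqrt(vh) + self.eps) + self.wd * p)


def _as_nchw(tensors) -> np.ndarray:
    """Stack ModelInput tensors / (H, W, C) arrays into an (N, C, H, W) batch."""
    arrs = []
    for t in tensors:
        a = np.asarray(getattr(t, "tensor", t), dtype=float)
        if a.ndim != 3:
            raise ValueError("each input must be (H, W, C)")
        arrs.append(a.transpose(2, 0, 1))
    return np.stack(arrs)


def train(model: Model, train_inputs, train_labels, val_inputs, val_labels,
          config: TrainConfig | None = None) -> dict:
    """Fit the model with AdamW + BCE under the published schedule.

    Returns a history dict with per-epoch train/val losses, accuracies and
    learning rate, plus the fully resolved config. Fully seeded: identical
    config and data reproduce the identical history.
    """
    config = config or TrainConfig()
    X = _as_nchw(train_inputs)
    y = np.asarray(train_labels, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    if len(val_inputs) == 0:
        raise ValueError("validation set must not be empty")
    Xv = _as_nchw(val_inputs)
    yv = np.asarray(val_labels, dtype=float)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    model._rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    opt = _AdamW(model, config.learning_rate, config.weight_decay)
    history = {"train_loss": [], "val_loss": [], "train_acc": [], "val_acc": [],
               "lr": [], "config": config.to_dict()}
    best_val = np.inf
    plateau_wait = early_wait = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            z = model.forward(X[idx], train=True)
            loss, gz = _bce_with_logits(z, y[idx])
            model.backward(gz)
            opt.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        probs = model.predict_proba(X)
        train_acc = float(np.mean((probs >= config.threshold) == (y == 1)))
        zv = model.forward(Xv, train=False)
        val_loss, _ = _bce_with_logits(zv, yv)
        val_acc = float(np.mean((_sigmoid(zv) >= config.threshold) == (yv == 1)))
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["train_acc"].append(train_acc)
        history["val_acc"].append(val_acc)
        history["lr"].append(opt.lr)

        if val_loss < best_val - config.min_improvement:
            best_val = val_loss
            plateau_wait = early_wait = 0
        else:
            plateau_wait += 1
            early_wait += 1
            if plateau_wait > config.plateau_patience:
                opt.lr *= config.plateau_factor
                plateau_wait = 0
            if early_wait > config.early_stop_patience:
                history["stopped_early"] = True
                history["stopped_epoch"] = epoch + 1
                break
    history.setdefault("stopped_early", False)
    history["epochs_run"] = len(history["train_loss"])
    return history


def evaluate(model: Model, inputs, labels, threshold: float = 0.5):
    """Thresholded predictions, confusion counts (cancer positive), metrics.

    Returns ``(ConfusionCounts, metrics_dict, predictions)``; invariant to
    sample order.
    """
    if len(inputs) == 0:
        raise ValueError("test set must not be empty")
    X = _as_nchw(inputs)
    y = np.asarray(labels, dtype=int)
    probs = model.predict_proba(X)
    pred = (probs >= threshold).astype(int)
    counts = ConfusionCounts(
        TP=int(np.sum((pred == 1) & (y == 1))),
        TN=int(np.sum((pred == 0) & (y == 0))),
        FP=int(np.sum((pred == 1) & (y == 0))),
        FN=int(np.sum((pred == 0) & (y == 1))),
    )
    return counts, classification_metrics(counts), pred


# ---------------------------------------------------------------------------
# Channel inflation and augmentation
# ---------------------------------------------------------------------------

def inflate_first_layer(weights: np.ndarray, target_channels: int = 36, seed: int = 0) -> np.ndarray:
    """Adapt 3-channel first-layer conv weights to ``target_channels``.

    Channels 1-3 of the result are bit-identical to the source; the
    remaining channels are drawn from the He normal initializer with the
    inflated layer's fan-in (``target_channels * kh * kw``), seeded.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 4 or w.shape[1] != 3:
        raise ValueError(f"expected (out, 3, kh, kw) weights, got shape {w.shape}")
    out_ch, _, kh, kw = w.shape
    if target_channels < 3:
        raise ValueError("target channel count must be >= 3")
    rng = np.random.default_rng(seed)
    new = np.empty((out_ch, target_channels, kh, kw), dtype=w.dtype)
    new[:, :3] = w
    new[:, 3:] = rng.normal(0.0, he_std(target_channels * kh * kw),
                            size=(out_ch, target_channels - 3, kh, kw))
    return new


def augment(tensor, op: str, seed: int = 0, **params):
    """Label-preserving augmentation applied jointly to all 36 channels.

    ``rotation`` rotates every channel by the same (seeded or given) angle;
    ``clahe`` applies contrast-limited adaptive histogram equalization per
    channel; ``blur`` applies a spatial Gaussian blur. Output shape and
    value range [0, 1] are preserved.
    """
    from scipy import ndimage

    t = np.asarray(getattr(tensor, "tensor", tensor), dtype=float)
    if t.ndim != 3:
        raise ValueError("augment expects an (H, W, C) tensor")
    rng = np.random.default_rng(seed)
    if op == "rotation":
        angle = params.get("angle")
        if angle is None:
            angle = float(rng.uniform(-180.0, 180.0))
        if angle % 360 == 0:
            out = t.copy()
        else:
            out = ndimage.rotate(t, angle, axes=(1, 0), reshape=False, order=1,
                                 mode="constant", cval=0.0)
    elif op == "clahe":
        from skimage.exposure import equalize_adapthist

        out = np.stack(
            [equalize_adapthist(np.clip(t[..., c], 0, 1)) for c in range(t.shape[2])],
            axis=-1,
        )
    elif op == "blur":
        sigma = float(params.get("sigma", rng.uniform(0.5, 1.5)))
        out = ndimage.gaussian_filter(t, sigma=(sigma, sigma, 0.0))
    else:
        raise ValueError(f"unknown augmentation op {op!r}")
    return np.clip(out, 0.0, 1.0)
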