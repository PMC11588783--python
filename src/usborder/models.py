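"""Compact numpy segmentation models exposing the adapter contract.

Two fixtures back the explainability and end-to-end tests:

* ``FixedLinearModel`` — a two-convolution network with hand-set weights.
  Its class scores are affine in the input, so every gradient used by
  Seg-Grad-CAM has a closed form that tests can check analytically.
* ``SmallUNet`` — a miniature encoder–decoder (one pooling level, one
  skip connection) trainable on CPU to high Dice on 2D speckle phantoms.

Both implement the :class:`ModelAdapter` contract: deterministic
per-pixel pre-softmax class scores, named internal activations, exact
gradients of any scalar with respect to a named activation, and a
"resume forward from a layer" entry point used by finite-difference
gradient checks.  Images are min-max normalized to [0, 1] on the way in.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class AdapterError(ValueError):
    """Unknown layer or broken adapter contract."""


def _minmax(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    lo, hi = x.min(), x.max()
    return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)


# ---------------------------------------------------------------- layers

class _Conv2d:
    """Same-padded 2D convolution (cross-correlation) via im2col."""

    def __init__(self, weight: np.ndarray, bias: np.ndarray):
        self.w = np.asarray(weight, dtype=np.float64)  # (Cout, Cin, k, k)
        self.b = np.asarray(bias, dtype=np.float64)
        self.k = self.w.shape[-1]
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    @staticmethod
    def init(rng, c_in, c_out, k):
        scale = np.sqrt(2.0 / (c_in * k * k))
        return _Conv2d(rng.normal(0, scale, (c_out, c_in, k, k)),
                       np.zeros(c_out))

    def _im2col(self, x):
        c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # (C, H, W, k, k) -> (H*W, C*k*k)
        return cols.transpose(1, 2, 0, 3, 4).reshape(h * w, -1)

    def forward(self, x):
        self._xshape = x.shape
        self._cols = self._im2col(x)
        c_out = self.w.shape[0]
        y = self._cols @ self.w.reshape(c_out, -1).T + self.b
        h, w = x.shape[1:]
        return y.reshape(h, w, c_out).transpose(2, 0, 1)

    def forward_pure(self, x):
        """Forward without touching caches (used by resume-forward paths)."""
        cols = self._im2col_of(x)
        c_out = self.w.shape[0]
        y = cols @ self.w.reshape(c_out, -1).T + self.b
        return y.reshape(x.shape[1], x.shape[2], c_out).transpose(2, 0, 1)

    def _im2col_of(self, x):
        saved_shape, saved_cols = self._xshape, self._cols
        cols = self._im2col(x)
        self._xshape, self._cols = saved_shape, saved_cols
        return cols

    def backward(self, dy, accumulate_grads=True):
        c_out = dy.shape[0]
        h, w = dy.shape[1:]
        dyf = dy.transpose(1, 2, 0).reshape(h * w, c_out)
        if accumulate_grads:
            self.dw += (dyf.T @ self._cols).reshape(self.w.shape)
            self.db += dyf.sum(axis=0)
        dcols = dyf @ self.w.reshape(c_out, -1)  # (H*W, Cin*k*k)
        c_in = self._xshape[0]
        p = self.k // 2
        dxp = np.zeros((c_in, h + 2 * p, w + 2 * p))
        dcols = dcols.reshape(h, w, c_in, self.k, self.k)
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, di:di + h, dj:dj + w] += dcols[:, :, :, di, dj].transpose(2, 0, 1)
        return dxp[:, p:p + h, p:p + w] if p else dxp

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dy):
        return dy * self.mask


def _avgpool2(x):
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def _avgpool2_back(dy, shape):
    c, h, w = shape
    return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0


def _up2(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _up2_back(dy):
    c, h, w = dy.shape
    return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


# ---------------------------------------------------------------- adapters

class ModelAdapter:
    """Contract every explainable segmentation model must satisfy.

    Subclasses cache the activations of the most recent :meth:`forward`;
    evaluation is deterministic (fixed weights, inference only).
    """

    layer_order: tuple = ()

    def layer_names(self):
        return tuple(self.layer_order)

    def _require_layer(self, layer):
        if layer not in self.layer_order:
            raise AdapterError(
                f"unknown layer {layer!r}; available: {list(self.layer_order)}")

    def forward(self, image) -> np.ndarray:
        raise NotImplementedError

    def predict_scores(self, image) -> np.ndarray:
        return self.forward(image)

    def predict_labels(self, image) -> np.ndarray:
        return np.argmax(self.forward(image), axis=0)

    def activations(self, layer) -> np.ndarray:
        self._require_layer(layer)
        return self._acts[layer]

    def grad_wrt(self, layer, d_scores) -> np.ndarray:
        """Exact gradient of ``sum(d_scores * scores)`` w.r.t. a named activation."""
        raise NotImplementedError

    def forward_from(self, layer, activation) -> np.ndarray:
        """Recompute scores treating ``activation`` as the named layer's output,
        holding everything upstream at its cached value."""
        raise NotImplementedError


class FixedLinearModel(ModelAdapter):
    """Affine two-layer model with deterministic hand-set weights.

    features = conv3x3(image); scores = conv1x1(features).  Because the
    head is linear, d(sum of selected class scores)/d(features_f) is the
    head weight times the pixel-set indicator — a closed form tests use
    as an oracle.
    """

    layer_order = ("features", "scores")

    def __init__(self, n_features: int = 4, n_classes: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.conv1 = _Conv2d(rng.normal(0, 0.5, (n_features, 1, 3, 3)),
                             rng.normal(0, 0.1, n_features))
        self.head = _Conv2d(rng.normal(0, 0.5, (n_classes, n_features, 1, 1)),
                            rng.normal(0, 0.1, n_classes))
        self.n_classes = n_classes
        self._acts = {}

    def forward(self, image):
        x = _minmax(getattr(image, "data", image))[None]
        a = self.conv1.forward(x)
        s = self.head.forward(a)
        self._acts = {"features": a, "scores": s}
        return s

    def grad_wrt(self, layer, d_scores):
        self._require_layer(layer)
        if layer == "scores":
            return np.asarray(d_scores, dtype=np.float64)
        return self.head.backward(np.asarray(d_scores, dtype=np.float64),
                                  accumulate_grads=False)

    def forward_from(self, layer, activation):
        self._require_layer(layer)
        if layer == "scores":
            return np.asarray(activation, dtype=np.float64)
        return self.head.forward_pure(np.asarray(activation, dtype=np.float64))


class SmallUNet(ModelAdapter):
    """Miniature encoder–decoder pixel classifier.

    The input image is presented as three channels — raw plus two
    Gaussian-smoothed views (sigma 2 and 4 voxels) — giving the first
    convolution a cheap multi-scale, speckle-suppressed look at the image.

    enc1: conv3x3(3->w) + ReLU            (full resolution)
    enc2: conv3x3(w->2w) + ReLU           (after 2x average pooling)
    features: conv3x3(3w->w) + ReLU       (upsampled bottleneck ++ skip)
    scores: conv1x1(w->C)

    ``features`` is the last convolutional layer before the classification
    head — the default target of Seg-Grad-CAM.
    """

    layer_order = ("enc1", "enc2", "features", "scores")

    def __init__(self, n_classes: int = 4, width: int = 12, seed: int = 0):
        rng = np.random.default_rng(seed)
        w = width
        self.conv1 = _Conv2d.init(rng, 3, w, 3)
        self.conv2 = _Conv2d.init(rng, w, 2 * w, 3)
        self.conv3 = _Conv2d.init(rng, 3 * w, w, 3)
        self.head = _Conv2d.init(rng, w, n_classes, 1)
        self.relu1, self.relu2, self.relu3 = _ReLU(), _ReLU(), _ReLU()
        self.n_classes = n_classes
        self.width = w
        self._acts = {}

    # -- forward -----------------------------------------------------

    def forward(self, image):
        from scipy import ndimage
        x2d = _minmax(getattr(image, "data", image))
        if x2d.shape[0] % 2 or x2d.shape[1] % 2:
            raise AdapterError("SmallUNet needs even spatial dimensions")
        x = np.stack([x2d, ndimage.gaussian_filter(x2d, 2.0),
                      ndimage.gaussian_filter(x2d, 4.0)])
        a1 = self.relu1.forward(self.conv1.forward(x))
        p = _avgpool2(a1)
        a2 = self.relu2.forward(self.conv2.forward(p))
        u = _up2(a2)
        cat = np.concatenate([u, a1], axis=0)
        f = self.relu3.forward(self.conv3.forward(cat))
        s = self.head.forward(f)
        self._acts = {"enc1": a1, "enc2": a2, "features": f, "scores": s}
        self._a1_shape = a1.shape
        return s

    # -- gradients ---------------------------------------------------

    def grad_wrt(self, layer, d_scores):
        self._require_layer(layer)
        ds = np.asarray(d_scores, dtype=np.float64)
        if layer == "scores":
            return ds
        df = self.head.backward(ds, accumulate_grads=False)
        if layer == "features":
            return df
        dcat = self.conv3.backward(self.relu3.backward(df),
                                   accumulate_grads=False)
        w2 = 2 * self.width
        du, da1_skip = dcat[:w2], dcat[w2:]
        da2 = _up2_back(du)
        if layer == "enc2":
            return da2
        dp = self.conv2.backward(self.relu2.backward(da2),
                                 accumulate_grads=False)
        da1 = _avgpool2_back(dp, self._a1_shape) + da1_skip
        return da1  # layer == "enc1"

    def backward_params(self, d_scores):
        """Full backprop accumulating weight gradients (training path)."""
        df = self.head.backward(np.asarray(d_scores, dtype=np.float64))
        dcat = self.conv3.backward(self.relu3.backward(df))
        w2 = 2 * self.width
        du, da1_skip = dcat[:w2], dcat[w2:]
        dp = self.conv2.backward(self.relu2.backward(_up2_back(du)))
        da1 = _avgpool2_back(dp, self._a1_shape) + da1_skip
        self.conv1.backward(self.relu1.backward(da1))

    def params(self):
        return (self.conv1.params() + self.conv2.params()
                + self.conv3.params() + self.head.params())

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    # -- resume-forward ----------------------------------------------

    def forward_from(self, layer, activation):
        self._require_layer(layer)
        a = np.asarray(activation, dtype=np.float64)
        if layer == "scores":
            return a
        if layer == "features":
            return self.head.forward_pure(a)
        if layer == "enc2":
            u = _up2(a)
            cat = np.concatenate([u, self._acts["enc1"]], axis=0)
            f = np.maximum(self.conv3.forward_pure(cat), 0.0)
            return self.head.forward_pure(f)
        # enc1: feeds both the pooled path and the skip connection
        p = _avgpool2(a)
        a2 = np.maximum(self.conv2.forward_pure(p), 0.0)
        cat = np.concatenate([_up2(a2), a], axis=0)
        f = np.maximum(self.conv3.forward_pure(cat), 0.0)
        return self.head.forward_pure(f)


# ---------------------------------------------------------------- training

def _softmax(s):
    e = np.exp(s - s.max(axis=0, keepdims=True))
    return e / e.sum(axis=0, keepdims=True)


def weighted_ce_grad(scores, target, class_weights):
    """Per-pixel class-weighted cross-entropy: loss and d(loss)/d(scores)."""
    p = _softmax(scores)
    n_pix = target.size
    w = np.asarray(class_weights, dtype=np.float64)[target]  # (H, W)
    logp = np.log(np.take_along_axis(p, target[None], axis=0)[0] + 1e-12)
    loss = -(w * logp).sum() / n_pix
    onehot = np.zeros_like(scores)
    np.put_along_axis(onehot, target[None], 1.0, axis=0)
    dscores = (p - onehot) * w[None] / n_pix
    return loss, dscores


def train_small_unet(images, labels, n_classes: int, steps: int = 800,
                     lr: float = 1e-2, seed: int = 0, class_weights=None,
                     batch_size: int = 2, lr_step_epochs: int = 10,
                     lr_gamma: float = 0.5, augment_flip: bool = True,
                     width: int = 12):
    """Train a :class:`SmallUNet` with Adam and a stepped learning rate.

    Defaults follow common medical-segmentation practice — learning rate
    halved every 10 epochs, batch size 2, vertical-flip augmentation,
    min-max input normalization and inverse-frequency class weighting of
    the cross-entropy — with the base learning rate (1e-2) sized for this
    very small network.  Fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    model = SmallUNet(n_classes=n_classes, width=width, seed=seed)
    if class_weights is None:
        class_weights = np.full(n_classes, 1.0 / n_classes)
    imgs = [np.asarray(getattr(im, "data", im), dtype=np.float64)
            for im in images]
    labs = [np.asarray(getattr(lb, "data", lb)) for lb in labels]
    n = len(imgs)
    steps_per_epoch = max(1, n // batch_size)
    # Adam state
    m = [np.zeros_like(p) for p, _ in model.params()]
    v = [np.zeros_like(p) for p, _ in model.params()]
    t = 0
    losses = []
    for step in range(steps):
        epoch = step // steps_per_epoch
        cur_lr = lr * (lr_gamma ** (epoch // lr_step_epochs))
        idx = rng.integers(0, n, size=batch_size)
        model.zero_grad()
        batch_loss = 0.0
        for i in idx:
            x, y = imgs[i], labs[i]
            if augment_flip and rng.random() < 0.5:
                x, y = x[::-1].copy(), y[::-1].copy()
            scores = model.forward(x)
            loss, ds = weighted_ce_grad(scores, y, class_weights)
            model.backward_params(ds)
            batch_loss += loss
        losses.append(batch_loss / batch_size)
        t += 1
        for j, (p, g) in enumerate(model.params()):
            g = g / batch_size
            m[j] = 0.9 * m[j] + 0.1 * g
            v[j] = 0.999 * v[j] + 0.001 * g * g
            mh = m[j] / (1 - 0.9 ** t)
            vh = v[j] / (1 - 0.999 ** t)
            p -= cur_lr * mh / (np.sqrt(vh) + 1e-8)
    return model, losses


def save_model(model: ModelAdapter, path):
    """Serialize a toy model's weights to an .npz checkpoint."""
    arrays = {}
    if isinstance(model, SmallUNet):
        kind = "small_unet"
        convs = {"conv1": model.conv1, "conv2": model.conv2,
                 "conv3": model.conv3, "head": model.head}
    elif isinstance(model, FixedLinearModel):
        kind = "fixed_linear"
        convs = {"conv1": model.conv1, "head": model.head}
    else:
        raise ValueError("only the shipped toy models are serializable")
    for name, conv in convs.items():
        arrays[f"{name}_w"] = conv.w
        arrays[f"{name}_b"] = conv.b
    arrays["kind"] = np.array(kind)
    arrays["n_classes"] = np.array(model.n_classes)
    np.savez(path, **arrays)


def load_model(path) -> ModelAdapter:
    """Rebuild a toy model from an .npz checkpoint written by :func:`save_model`."""
    data = np.load(path, allow_pickle=False)
    kind = str(data["kind"])
    n_classes = int(data["n_classes"])
    if kind == "small_unet":
        model = SmallUNet(n_classes=n_classes, width=data["conv1_w"].shape[0])
        names = {"conv1": model.conv1, "conv2": model.conv2,
                 "conv3": model.conv3, "head": model.head}
    else:
        model = FixedLinearModel(n_classes=n_classes,
                                 n_features=data["conv1_w"].shape[0])
        names = {"conv1": model.conv1, "head": model.head}
    for name, conv in names.items():
        conv.w = data[f"{name}_w"].astype(np.float64)
        conv.b = data[f"{name}_b"].astype(np.float64)
    return model


def toy_model_fixture(kind: str = "fixed_linear", seed: int = 0,
                      n_classes: int = 4, **train_kwargs):
    """Build a deterministic model fixture.

    ``fixed_linear`` returns an untrained affine model with hand-set
    weights (for gradient oracles); ``small_unet`` returns an untrained
    miniature encoder–decoder (train it with :func:`train_small_unet`).
    """
    if kind == "fixed_linear":
        return FixedLinearModel(n_classes=n_classes, seed=seed)
    if kind == "small_unet":
        return SmallUNet(n_classes=n_classes, seed=seed, **train_kwargs)
    raise ValueError(f"unknown model fixture kind {kind!r}")
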