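"""Encoder-decoder CNN (U-Net) for pixel-wise bladder / non-bladder labelling.

A five-level U-Net: the encoder has 10 convolutional layers (3x3 kernels,
ReLU, two per level) with 4 max-pooling stages and dropout regularisation;
the decoder mirrors it with 4 nearest-neighbour upsampling stages, skip
concatenations and 9 convolutional layers (eight 3x3 plus the final 1x1),
ending in a two-class softmax.  Weights are Glorot-uniform initialised and
trained with Adam on a weighted categorical cross-entropy,

    L = (1/n) sum_i sum_j -y_ij log(yhat_ij) w_j ,   w_j = max_k(n_k) / n_j ,

whose class weights balance the bladder (minority) against the background.
Training data is expanded by random elastic deformation, and evaluation uses
subject-level k-fold cross-validation so that no volunteer's images appear
in both the training and validation split.

The network is implemented directly in NumPy (im2col convolutions with
hand-written backprop), sized for CPU training on reduced-resolution
phantom images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .evaluation import dice

__all__ = [
    "UNetSpec",
    "TrainConfig",
    "UNet",
    "TrainingDivergedError",
    "class_weights",
    "weighted_cce",
    "elastic_augment",
    "augment_dataset",
    "subject_folds",
    "train_fold",
    "train",
    "predict",
    "save_weights",
    "load_weights",
    "pad_to_pool_compatible",
]

_LEVELS = 5  # 4 pooling stages


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes NaN/inf."""


@dataclass(frozen=True)
class UNetSpec:
    """Architecture hyperparameters.

    ``base_features`` sets the first-level feature-map count; deeper levels
    double it (the standard U-Net ladder).  Input height/width must be
    divisible by 16 (4 pooling stages); :func:`pad_to_pool_compatible` pads
    arbitrary images minimally and symmetrically.
    """

    base_features: int = 8
    classes: int = 2
    dropout_rate: float = 0.5

    def feature_widths(self) -> list[int]:
        return [self.base_features * 2**i for i in range(_LEVELS)]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings: Adam with initial learning rate 1e-5 by default."""

    learning_rate: float = 1e-5
    epochs: int = 30
    folds: int = 5
    augmentation_factor: int = 10
    seed: int = 0


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def class_weights(label_counts) -> np.ndarray:
    """Balancing weights w_j = max(counts) / count_j (>= 1)."""
    counts = np.asarray(label_counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("every class must have a positive pixel count")
    return counts.max() / counts


def weighted_cce(y, y_hat, weights, eps: float = 1e-7) -> float:
    """Weighted categorical cross-entropy over samples.

    ``y`` and ``y_hat`` are (n, m) one-hot labels and predicted
    probabilities; ``weights`` is per-class (m,) or per-sample-and-class
    (n, m).  With unit weights this is the ordinary categorical
    cross-entropy.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"label/prediction shapes differ: {y.shape} vs {y_hat.shape}")
    w = np.asarray(weights, dtype=float)
    w = np.broadcast_to(w, y.shape)
    y_hat = np.clip(y_hat, eps, 1.0)
    return float(np.mean(np.sum(-y * np.log(y_hat) * w, axis=-1)))


# ---------------------------------------------------------------------------
# Primitive layers (channels-first single sample: (C, H, W))
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    cols = sliding_window_view(xp, (k, k), axis=(1, 2))  # (C, H, W, k, k)
    return cols.transpose(0, 3, 4, 1, 2).reshape(c * k * k, h * w)


def _conv_forward(x, W, b):
    co, ci, k, _ = W.shape
    cols = _im2col(x, k)
    out = (W.reshape(co, -1) @ cols + b[:, None]).reshape(co, x.shape[1], x.shape[2])
    return out, cols


def _conv_backward(dout, cols, W, x_shape):
    co, ci, k, _ = W.shape
    c, h, w = x_shape
    dflat = dout.reshape(co, -1)
    dW = (dflat @ cols.T).reshape(W.shape)
    db = dflat.sum(axis=1)
    dcols = (W.reshape(co, -1).T @ dflat).reshape(c, k, k, h, w)
    p = k // 2
    dxp = np.zeros((c, h + 2 * p, w + 2 * p))
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + h, j : j + w] += dcols[:, i, j]
    return dW, db, dxp[:, p : p + h, p : p + w]


def _maxpool2(x):
    c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    r = x.reshape(c, h2, 2, w2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h2, w2, 4)
    idx = r.argmax(-1)
    out = np.take_along_axis(r, idx[..., None], -1)[..., 0]
    return out, (idx, x.shape)


def _maxpool2_backward(dout, cache):
    idx, (c, h, w) = cache
    h2, w2 = h // 2, w // 2
    dr = np.zeros((c, h2, w2, 4))
    np.put_along_axis(dr, idx[..., None], dout[..., None], -1)
    return dr.reshape(c, h2, w2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h, w)


def _upsample2(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample2_backward(dout):
    c, h, w = dout.shape
    return dout.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

class UNet:
    """Five-level U-Net with NumPy forward/backward passes.

    Parameters live in ``self.params`` (name -> array).  ``forward`` caches
    everything needed by ``backward``; both operate on a single
    channels-first sample.
    """

    def __init__(self, spec: UNetSpec | None = None, seed: int = 0):
        self.spec = spec or UNetSpec()
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        f = self.spec.feature_widths()
        ci = 1
        for i in range(_LEVELS):
            self._add_conv(rng, f"enc{i}_conv1", ci, f[i], 3)
            self._add_conv(rng, f"enc{i}_conv2", f[i], f[i], 3)
            ci = f[i]
        for i in range(_LEVELS - 2, -1, -1):
            cin = f[i + 1] + f[i]  # upsampled below + skip
            self._add_conv(rng, f"dec{i}_conv1", cin, f[i], 3)
            self._add_conv(rng, f"dec{i}_conv2", f[i], f[i], 3)
        self._add_conv(rng, "final", f[0], self.spec.classes, 1)

    def _add_conv(self, rng, name, ci, co, k):
        # Glorot uniform: limit = sqrt(6 / (fan_in + fan_out))
        fan_in, fan_out = ci * k * k, co * k * k
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.params[f"{name}_W"] = rng.uniform(-limit, limit, size=(co, ci, k, k))
        self.params[f"{name}_b"] = np.zeros(co)

    def _conv_relu(self, name, x, cache, relu=True):
        out, cols = _conv_forward(x, self.params[f"{name}_W"], self.params[f"{name}_b"])
        if relu:
            out = np.maximum(out, 0.0)
        cache[name] = (cols, x.shape, out > 0 if relu else None)
        return out

    def _conv_relu_backward(self, name, d, cache, grads):
        cols, x_shape, relu_mask = cache[name]
        if relu_mask is not None:
            d = d * relu_mask
        dW, db, dx = _conv_backward(d, cols, self.params[f"{name}_W"], x_shape)
        grads[f"{name}_W"] = grads.get(f"{name}_W", 0) + dW
        grads[f"{name}_b"] = grads.get(f"{name}_b", 0) + db
        return dx

    def forward(self, image: np.ndarray, train: bool = False, rng=None):
        """Logits (classes, H, W) for an (H, W) image in [0, 1]."""
        x = np.asarray(image, dtype=float)
        if x.ndim != 2:
            raise ValueError("expected a single-channel (H, W) image")
        if x.shape[0] % 16 or x.shape[1] % 16:
            raise ValueError("input dims must be divisible by 16; pad first")
        cache: dict = {"train": train}
        h = x[None]
        skips = []
        for i in range(_LEVELS):
            h = self._conv_relu(f"enc{i}_conv1", h, cache)
            h = self._conv_relu(f"enc{i}_conv2", h, cache)
            if train and self.spec.dropout_rate > 0:
                keep = (rng or np.random.default_rng()).random(h.shape) >= self.spec.dropout_rate
                h = h * keep / (1.0 - self.spec.dropout_rate)
                cache[f"drop{i}"] = keep
            if i < _LEVELS - 1:
                skips.append(h)
                h, cache[f"pool{i}"] = _maxpool2(h)
        for i in range(_LEVELS - 2, -1, -1):
            h = _upsample2(h)
            cache[f"cat{i}_split"] = skips[i].shape[0]
            h = np.concatenate([skips[i], h], axis=0)
            h = self._conv_relu(f"dec{i}_conv1", h, cache)
            h = self._conv_relu(f"dec{i}_conv2", h, cache)
        logits = self._conv_relu("final", h, cache, relu=False)
        self._cache = cache
        return logits

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Parameter gradients from d(loss)/d(logits) of the last forward."""
        cache = self._cache
        grads: dict[str, np.ndarray] = {}
        d = self._conv_relu_backward("final", dlogits, cache, grads)
        dskips: dict[int, np.ndarray] = {}
        for i in range(_LEVELS - 1):  # decoder levels in reverse forward order
            d = self._conv_relu_backward(f"dec{i}_conv2", d, cache, grads)
            d = self._conv_relu_backward(f"dec{i}_conv1", d, cache, grads)
            split = cache[f"cat{i}_split"]
            dskips[i] = d[:split]
            d = _upsample2_backward(d[split:])
        for i in range(_LEVELS - 1, -1, -1):
            if cache["train"] and f"drop{i}" in cache:
                d = d * cache[f"drop{i}"] / (1.0 - self.spec.dropout_rate)
            d = self._conv_relu_backward(f"enc{i}_conv2", d, cache, grads)
            d = self._conv_relu_backward(f"enc{i}_conv1", d, cache, grads)
            if i > 0:
                d = _maxpool2_backward(d, cache[f"pool{i - 1}"])
                d = d + dskips[i - 1]
        return grads


def _softmax(logits):
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def _loss_and_grad(logits, target_mask, weights, eps=1e-7):
    """Weighted softmax cross-entropy over pixels and its logit gradient."""
    p = _softmax(logits)
    y = np.stack([~target_mask, target_mask]).astype(float)
    wpix = weights[1] * target_mask + weights[0] * ~target_mask
    npix = target_mask.size
    loss = float(np.sum(-y * np.log(np.clip(p, eps, 1.0)) * wpix) / npix)
    dlogits = wpix * (p - y) / npix
    return loss, dlogits


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Augmentation, folds, training
# ---------------------------------------------------------------------------

def elastic_augment(
    image: np.ndarray,
    mask: np.ndarray,
    grid_sigma: float = 20.0,
    magnitude: float = 4.0,
    seed: int = 0,
):
    """One random smooth elastic deformation applied to an image/mask pair.

    A dense Gaussian-smoothed random displacement field (smoothing scale
    ``grid_sigma`` px, RMS amplitude ``magnitude`` px) warps the image with
    bilinear and the mask with nearest-neighbour interpolation, identically.
    Deterministic per seed; ``magnitude=0`` is the identity.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask must share a shape")
    if magnitude == 0:
        return image.copy(), mask.copy()
    rng = np.random.default_rng(seed)
    disp = []
    for _ in range(2):
        f = ndimage.gaussian_filter(rng.standard_normal(image.shape), grid_sigma)
        std = f.std()
        disp.append(f / std * magnitude if std > 0 else f)
    rr, cc = np.meshgrid(
        np.arange(image.shape[0]), np.arange(image.shape[1]), indexing="ij"
    )
    coords = [rr + disp[0], cc + disp[1]]
    warped = ndimage.map_coordinates(image, coords, order=1, mode="reflect")
    warped_mask = ndimage.map_coordinates(
        mask.astype(np.uint8), coords, order=0, mode="reflect"
    ).astype(mask.dtype)
    return warped, warped_mask


def augment_dataset(images, masks, factor: int = 10, seed: int = 0, **kwargs):
    """Expand a dataset ``factor``-fold: each original plus factor-1 warps."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    out_imgs, out_masks = [], []
    for img, msk in zip(images, masks):
        out_imgs.append(np.asarray(img, dtype=float))
        out_masks.append(np.asarray(msk))
        for _ in range(factor - 1):
            wi, wm = elastic_augment(
                img, msk, seed=int(rng.integers(0, 2**31 - 1)), **kwargs
            )
            out_imgs.append(wi)
            out_masks.append(wm)
    return out_imgs, out_masks


def subject_folds(subject_ids, k: int, seed: int = 0) -> dict:
    """Partition distinct subjects (not images) into k folds.

    Returns ``{subject_id: fold_index}``; every image of a subject shares its
    fold, so folds are disjoint at the subject level.
    """
    subjects = sorted(set(subject_ids))
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    assignment = {}
    for fold, chunk in enumerate(np.array_split(np.arange(len(order)), k)):
        for j in chunk:
            assignment[order[j]] = fold
    return assignment


def pad_to_pool_compatible(image: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Minimal symmetric zero-padding of an image to dims divisible by 16."""
    h, w = image.shape
    ph, pw = (-h) % 16, (-w) % 16
    pads = ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2))
    return np.pad(image, pads), pads


def _val_dice(model, images, masks):
    scores = [dice(predict(model, im), mk) for im, mk in zip(images, masks)]
    return float(np.mean(scores)) if scores else float("nan")


def train_fold(
    train_images,
    train_masks,
    val_images,
    val_masks,
    spec: UNetSpec | None = None,
    config: TrainConfig | None = None,
) -> tuple[UNet, dict]:
    """Train one model on a fixed train/validation split.

    Images are (H, W) with intensities in [0, 255] and dims divisible by 16;
    masks are boolean.  Runs plain per-sample Adam updates for
    ``config.epochs`` epochs with the class-balanced weighted cross-entropy.
    Returns the model and a history dict (per-epoch mean loss, final
    validation Dice).

    Raises
    ------
    TrainingDivergedError
        If the loss turns NaN/inf.
    """
    spec = spec or UNetSpec()
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    model = UNet(spec, seed=config.seed)
    opt = _Adam(model.params, config.learning_rate)

    imgs = [np.asarray(im, dtype=float) / 255.0 for im in train_images]
    msks = [np.asarray(mk).astype(bool) for mk in train_masks]
    counts = np.array(
        [sum((~m).sum() for m in msks), sum(m.sum() for m in msks)], dtype=float
    )
    weights = class_weights(np.maximum(counts, 1.0))

    history = {"loss": []}
    for epoch in range(config.epochs):
        order = rng.permutation(len(imgs))
        losses = []
        for idx in order:
            logits = model.forward(imgs[idx], train=True, rng=rng)
            loss, dlogits = _loss_and_grad(logits, msks[idx], weights)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"loss became {loss} at epoch {epoch}, sample {idx}"
                )
            grads = model.backward(dlogits)
            opt.step(model.params, grads)
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
    history["val_dice"] = _val_dice(model, val_images, val_masks)
    return model, history


def train(
    images,
    masks,
    subject_ids,
    spec: UNetSpec | None = None,
    config: TrainConfig | None = None,
) -> dict:
    """Subject-level k-fold cross-validated training.

    Returns ``{"per_fold_dice": [...], "models": [...], "folds": {...}}``.
    """
    config = config or TrainConfig()
    assignment = subject_folds(subject_ids, config.folds, seed=config.seed)
    fold_of = np.array([assignment[s] for s in subject_ids])
    per_fold, models = [], []
    for fold in range(config.folds):
        tr = fold_of != fold
        va = ~tr
        model, hist = train_fold(
            [im for im, t in zip(images, tr) if t],
            [mk for mk, t in zip(masks, tr) if t],
            [im for im, v in zip(images, va) if v],
            [mk for mk, v in zip(masks, va) if v],
            spec,
            config,
        )
        per_fold.append(hist["val_dice"])
        models.append(model)
    return {"per_fold_dice": per_fold, "models": models, "folds": assignment}


def predict(model: UNet, image: np.ndarray) -> np.ndarray:
    """Binary bladder mask: per-pixel argmax of the softmax output.

    Accepts any (H, W) image with intensities in [0, 255]; pads to
    pooling-compatible dims internally and crops the prediction back.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel (H, W) image")
    scaled = image / 255.0 if image.max() > 1.5 else image
    padded, pads = pad_to_pool_compatible(scaled)
    logits = model.forward(padded, train=False)
    pred = logits.argmax(axis=0).astype(bool)
    (pt, pb), (pl, pr) = pads
    return pred[pt : pred.shape[0] - pb or None, pl : pred.shape[1] - pr or None]


def save_weights(model: UNet, path) -> None:
    np.savez(
        path,
        __base_features=model.spec.base_features,
        __classes=model.spec.classes,
        __dropout=model.spec.dropout_rate,
        **model.params,
    )


def load_weights(path) -> UNet:
    data = np.load(path)
    spec = UNetSpec(
        base_features=int(data["__base_features"]),
        classes=int(data["__classes"]),
        dropout_rate=float(data["__dropout"]),
    )
    model = UNet(spec)
    for k in model.params:
        model.params[k] = data[k]
    return model
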