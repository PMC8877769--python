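"""Desk-scale trainable models for both HC-estimation routes.

Two miniature networks stand behind the pipeline:

* ``TinySegNet`` — an encoder-decoder with skip connections (one 3x3
  conv + ReLU per level, 2x2 max pooling / nearest upsampling, sigmoid
  1-channel output) trained with the soft-Dice loss.
* ``TinyRegNet`` — a small conv stack with global average pooling,
  inverted dropout, and a single linear output, trained on HC targets
  normalized by the maximum training HC, with MAE, MSE or Huber loss.

The pipeline API is backbone-agnostic: anything with a ``predict_proba``
(segmentation) or ``predict_scalar`` (regression) method over image
batches can be plugged into the two ``estimate_hc_*`` routes, so full-size
networks can replace the miniatures without touching the rest.

Scikit-learn-style wrappers (:class:`SegmentationHC`,
:class:`RegressionHC`) expose fit/predict and compose with sklearn
model-selection utilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from skimage.transform import resize as _resize

from . import nn
from .errors import (
    ConfigurationError,
    EllipseFitError,
    InvalidInputError,
    InvalidParameterError,
)
from .geometry import EllipseParams, PixelSpacing, hc_mm, fit_ellipse, rescale_ellipse
from .postproc import postprocess_to_points

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionLossSpec",
    "TrainConfig",
    "HCPrediction",
    "regression_loss",
    "dice_loss",
    "normalize_hc",
    "denormalize_hc",
    "build_tiny_segnet",
    "build_tiny_regnet",
    "count_parameters",
    "train",
    "estimate_hc_segmentation",
    "estimate_hc_regression",
    "SegmentationHC",
    "RegressionHC",
]

count_parameters = nn.count_parameters


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionLossSpec:
    """Choice of regression loss; ``delta`` is the Huber threshold."""

    kind: Literal["MAE", "MSE", "Huber"] = "MAE"
    delta: float = 1.0

    def __post_init__(self):
        if self.kind not in ("MAE", "MSE", "Huber"):
            raise InvalidParameterError(f"unknown loss kind {self.kind!r}")
        if self.delta <= 0:
            raise InvalidParameterError(f"Huber delta must be positive, got {self.delta}")


@dataclass
class TrainConfig:
    """Training protocol and normalization constants.

    Defaults follow the reference protocol (Adam, lr 1e-4, batch 16); the
    epoch default is desk-scale (20 rather than 100).  ``hc_norm_constant``
    must be set from the *training* split before regression targets are
    normalized.
    """

    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 20
    optimizer: str = "adam"
    dropout_keep: float = 0.3
    seed: int = 0
    input_size: tuple[int, int] = (64, 64)
    hc_norm_constant: float | None = None

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise InvalidParameterError("learning_rate, batch_size, epochs must be positive")
        if not 0 < self.dropout_keep <= 1:
            raise InvalidParameterError(f"dropout_keep must be in (0, 1], got {self.dropout_keep}")
        if self.optimizer.lower() != "adam":
            raise InvalidParameterError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class HCPrediction:
    """One per-image HC estimate with its provenance."""

    image_id: str
    hc_mm: float | None
    route: Literal["segmentation", "regression"]
    ellipse: EllipseParams | None = None
    error: str | None = None

    @property
    def success(self) -> bool:
        return self.hc_mm is not None


# ---------------------------------------------------------------------------
# Losses (value + gradient wrt prediction; public API returns the value)
# ---------------------------------------------------------------------------

def _reg_loss_grad(spec: RegressionLossSpec, pred: np.ndarray, gt: np.ndarray):
    e = pred - gt
    n = e.size
    if spec.kind == "MAE":
        return float(np.abs(e).mean()), np.sign(e) / n
    if spec.kind == "MSE":
        return float((e**2).mean()), 2.0 * e / n
    d = spec.delta
    small = np.abs(e) < d
    vals = np.where(small, 0.5 * e**2, d * (np.abs(e) - d / 2.0))
    grad = np.where(small, e, d * np.sign(e)) / n
    return float(vals.mean()), grad


def regression_loss(spec: RegressionLossSpec, pred: Sequence[float], gt: Sequence[float]) -> float:
    """Mean per-element MAE / MSE / Huber loss.

    Huber uses the quadratic branch e^2/2 for |e| < delta and the linear
    branch delta*(|e| - delta/2) otherwise; the branches agree (delta^2/2)
    at |e| = delta.
    """
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gt, dtype=float)
    if p.shape != g.shape or p.size == 0:
        raise InvalidInputError(f"pred and gt must be nonempty with equal shapes, got {p.shape} vs {g.shape}")
    return _reg_loss_grad(spec, p, g)[0]


_DICE_SMOOTH = 1.0


def _dice_loss_grad(prob: np.ndarray, gt: np.ndarray):
    S = float((prob * gt).sum())
    P = float(prob.sum())
    G = float(gt.sum())
    num = 2.0 * S + _DICE_SMOOTH
    den = P + G + _DICE_SMOOTH
    loss = 1.0 - num / den
    grad = -(2.0 * gt * den - num) / den**2
    return loss, grad


def dice_loss(prob_map: np.ndarray, gt_mask: np.ndarray) -> float:
    """Soft-Dice loss 1 - (2 sum(p*g) + 1) / (sum(p) + sum(g) + 1).

    Sums run over the whole batch; the +1 smoothing keeps the loss defined
    for empty masks.
    """
    p = np.asarray(prob_map, dtype=float)
    g = np.asarray(gt_mask, dtype=float)
    if p.shape != g.shape:
        raise InvalidInputError(f"shape mismatch: {p.shape} vs {g.shape}")
    if p.size == 0 or np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise InvalidInputError("probabilities must be nonempty and in [0, 1]")
    return _dice_loss_grad(p, g)[0]


def soft_dice(prob_map: np.ndarray, gt_mask: np.ndarray) -> float:
    """Soft-Dice coefficient (1 - dice_loss)."""
    return 1.0 - dice_loss(prob_map, gt_mask)


# ---------------------------------------------------------------------------
# HC target normalization
# ---------------------------------------------------------------------------

def normalize_hc(hc_mm_value, config: TrainConfig):
    """Scale HC by the maximum training HC (targets end up in (0, 1])."""
    if config.hc_norm_constant is None:
        raise ConfigurationError("hc_norm_constant unset; derive it from the training split first")
    return np.asarray(hc_mm_value, dtype=float) / config.hc_norm_constant


def denormalize_hc(value, config: TrainConfig):
    """Inverse of :func:`normalize_hc`."""
    if config.hc_norm_constant is None:
        raise ConfigurationError("hc_norm_constant unset; derive it from the training split first")
    return np.asarray(value, dtype=float) * config.hc_norm_constant


# ---------------------------------------------------------------------------
# Image preprocessing shared by both routes
# ---------------------------------------------------------------------------

def preprocess_images(images: np.ndarray, input_size: tuple[int, int]) -> np.ndarray:
    """Per-image z-score normalization + resize to the network input size.

    Returns an (N, 1, H, W) float array.  Per-image statistics are used so
    a single image can be processed without dataset-level state.
    """
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    out = np.empty((arr.shape[0], 1, input_size[0], input_size[1]))
    for i, img in enumerate(arr):
        z = (img - img.mean()) / (img.std() + 1e-8)
        out[i, 0] = _resize(z, input_size, order=1, anti_aliasing=True, preserve_range=True)
    return out


def resize_mask(mask: np.ndarray, input_size: tuple[int, int]) -> np.ndarray:
    """Binary-preserving mask resize (bilinear then 0.5 threshold)."""
    r = _resize(mask.astype(float), input_size, order=1, anti_aliasing=False, preserve_range=True)
    return (r >= 0.5).astype(float)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class TinySegNet:
    """Miniature encoder-decoder with skip connections and sigmoid output."""

    def __init__(self, depth: int = 3, base_filters: int = 8, in_ch: int = 1,
                 seed: int = 0, input_size: tuple[int, int] = (64, 64)):
        h, w = input_size
        if h % (2**depth) or w % (2**depth):
            raise InvalidParameterError(
                f"input size {input_size} must be divisible by 2^depth = {2**depth}"
            )
        self.depth = depth
        self.input_size = tuple(input_size)
        rng = np.random.default_rng(seed)
        f = [base_filters * 2**i for i in range(depth + 1)]
        self.enc = [nn.Conv2D(in_ch if i == 0 else f[i - 1], f[i], 3, rng) for i in range(depth)]
        self.bott = nn.Conv2D(f[depth - 1], f[depth], 3, rng)
        self.dec = [
            nn.Conv2D(f[i + 1] + f[i], f[i], 3, rng) for i in reversed(range(depth))
        ]
        self.head = nn.Conv2D(f[0], 1, 1, rng)
        self.pools = [nn.MaxPool2() for _ in range(depth)]
        self.ups = [nn.Upsample2() for _ in range(depth)]
        self.relus_e = [nn.ReLU() for _ in range(depth)]
        self.relu_b = nn.ReLU()
        self.relus_d = [nn.ReLU() for _ in range(depth)]
        self.sig = nn.Sigmoid()
        self.layers = self.enc + [self.bott] + self.dec + [self.head]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        h = x
        for conv, relu, pool in zip(self.enc, self.relus_e, self.pools):
            h = relu.forward(conv.forward(h))
            skips.append(h)
            h = pool.forward(h)
        h = self.relu_b.forward(self.bott.forward(h))
        self._skip_ch = [s.shape[1] for s in skips]
        for conv, relu, up, skip in zip(self.dec, self.relus_d, self.ups, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([h, skip], axis=1)
            h = relu.forward(conv.forward(h))
        return self.sig.forward(self.head.forward(h))[:, 0]

    def backward(self, dprob: np.ndarray) -> None:
        d = self.sig.backward(dprob[:, None])
        d = self.head.backward(d)
        dskips = []
        for conv, relu, up, ch in zip(
            reversed(self.dec), reversed(self.relus_d), reversed(self.ups),
            self._skip_ch,
        ):
            d = conv.backward(relu.backward(d))
            d, dskip = d[:, :-ch], d[:, -ch:]
            dskips.append(dskip)
            d = up.backward(d)
        d = self.bott.backward(self.relu_b.backward(d))
        for conv, relu, pool, dskip in zip(
            reversed(self.enc), reversed(self.relus_e), reversed(self.pools),
            reversed(dskips),
        ):
            d = pool.backward(d) + dskip
            d = conv.backward(relu.backward(d))

    def parameters(self):
        return [p for layer in self.layers for p in layer.params()]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads()]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)


class TinyRegNet:
    """Small conv stack + global average pooling + dropout + linear output."""

    def __init__(self, n_blocks: int = 3, base_filters: int = 8, in_ch: int = 1,
                 dropout_keep: float = 0.3, seed: int = 0,
                 input_size: tuple[int, int] = (64, 64)):
        h, w = input_size
        if h % (2**n_blocks) or w % (2**n_blocks):
            raise InvalidParameterError(
                f"input size {input_size} must be divisible by 2^n_blocks = {2**n_blocks}"
            )
        self.input_size = tuple(input_size)
        rng = np.random.default_rng(seed)
        f = [base_filters * 2**i for i in range(n_blocks + 1)]
        self.convs = [nn.Conv2D(in_ch if i == 0 else f[i - 1], f[i], 3, rng) for i in range(n_blocks)]
        self.top = nn.Conv2D(f[n_blocks - 1], f[n_blocks], 3, rng)
        self.pools = [nn.MaxPool2() for _ in range(n_blocks)]
        self.relus = [nn.ReLU() for _ in range(n_blocks)]
        self.relu_top = nn.ReLU()
        self.gap = nn.GlobalAvgPool()
        self.drop = nn.Dropout(dropout_keep, np.random.default_rng(seed + 1))
        self.fc = nn.Dense(f[n_blocks], 1, rng)
        self.layers = self.convs + [self.top, self.fc]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for conv, relu, pool in zip(self.convs, self.relus, self.pools):
            h = pool.forward(relu.forward(conv.forward(h)))
        h = self.relu_top.forward(self.top.forward(h))
        h = self.gap.forward(h)
        h = self.drop.forward(h, train=train)
        return self.fc.forward(h)[:, 0]

    def backward(self, dout: np.ndarray) -> None:
        d = self.fc.backward(dout[:, None])
        d = self.drop.backward(d)
        d = self.gap.backward(d)
        d = self.top.backward(self.relu_top.backward(d))
        for conv, relu, pool in zip(reversed(self.convs), reversed(self.relus), reversed(self.pools)):
            d = conv.backward(relu.backward(pool.backward(d)))

    def parameters(self):
        return [p for layer in self.layers for p in layer.params()]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads()]

    def predict_scalar(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)


def build_tiny_segnet(config: TrainConfig, depth: int = 3, base_filters: int = 8) -> TinySegNet:
    """Construct the miniature segmentation network for a training config."""
    return TinySegNet(depth=depth, base_filters=base_filters, seed=config.seed,
                      input_size=config.input_size)


def build_tiny_regnet(config: TrainConfig, n_blocks: int = 3, base_filters: int = 8) -> TinyRegNet:
    """Construct the miniature regression network for a training config."""
    return TinyRegNet(n_blocks=n_blocks, base_filters=base_filters,
                      dropout_keep=config.dropout_keep, seed=config.seed,
                      input_size=config.input_size)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(
    model,
    inputs: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig,
    loss: RegressionLossSpec | Literal["dice"] = "dice",
    val: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Mini-batch Adam training; returns per-epoch loss traces.

    ``inputs`` is (N, 1, H, W) already preprocessed; ``targets`` is
    (N, H, W) masks for the Dice loss or (N,) normalized scalars for a
    :class:`RegressionLossSpec`.  Fully deterministic given ``config.seed``.
    """
    x = np.asarray(inputs, dtype=float)
    t = np.asarray(targets, dtype=float)
    if x.shape[0] == 0:
        raise InvalidInputError("empty training set")
    if x.shape[0] != t.shape[0]:
        raise InvalidInputError(f"inputs/targets length mismatch: {x.shape[0]} vs {t.shape[0]}")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    trace: dict = {"train_loss": [], "val_loss": []}
    n = x.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            out = model.forward(x[idx], train=True)
            if loss == "dice":
                lval, grad = _dice_loss_grad(out, t[idx])
            else:
                lval, grad = _reg_loss_grad(loss, out, t[idx])
            model.backward(grad)
            opt.step(model.gradients())
            losses.append(lval)
        trace["train_loss"].append(float(np.mean(losses)))
        if val is not None:
            xv, tv = val
            outv = model.forward(np.asarray(xv, dtype=float), train=False)
            if loss == "dice":
                trace["val_loss"].append(_dice_loss_grad(outv, np.asarray(tv, float))[0])
            else:
                trace["val_loss"].append(_reg_loss_grad(loss, outv, np.asarray(tv, float))[0])
    return trace


# ---------------------------------------------------------------------------
# The two estimation routes
# ---------------------------------------------------------------------------

def estimate_hc_segmentation(
    image: np.ndarray,
    model,
    spacing: PixelSpacing,
    image_id: str = "",
    threshold: float = 0.5,
) -> HCPrediction:
    """Segmentation route: image -> prob map -> cleanup -> ellipse fit -> HC (mm).

    The ellipse fitted at network resolution is mapped back to the native
    grid through the exact diagonal transform before the mm conversion.
    An unusable segmentation yields a failed prediction, not an exception.
    """
    img = np.asarray(image, dtype=float)
    H, W = img.shape
    in_h, in_w = model.input_size
    x = preprocess_images(img, (in_h, in_w))
    prob = model.predict_proba(x)[0]
    try:
        pts = postprocess_to_points(prob, threshold)
        e_small = fit_ellipse(pts)
        fx, fy = W / in_w, H / in_h
        e = rescale_ellipse(e_small, fx, fy)
        # pixel-center alignment of the resize: x_native = fx*x + (fx-1)/2
        e = EllipseParams(e.cx + (fx - 1) / 2.0, e.cy + (fy - 1) / 2.0, e.a, e.b, e.theta)
        return HCPrediction(image_id, hc_mm(e, spacing), "segmentation", ellipse=e)
    except EllipseFitError as exc:
        logger.warning("segmentation route failed for %r: %s", image_id, exc)
        return HCPrediction(image_id, None, "segmentation", error=str(exc))


def estimate_hc_regression(
    image: np.ndarray,
    model,
    config: TrainConfig,
    image_id: str = "",
) -> HCPrediction:
    """Regression route: image -> scalar network output -> denormalized HC (mm)."""
    if config.hc_norm_constant is None:
        raise ConfigurationError("hc_norm_constant unset; fit on a training split first")
    x = preprocess_images(np.asarray(image, dtype=float), config.input_size)
    out = float(model.predict_scalar(x)[0])
    return HCPrediction(image_id, float(denormalize_hc(out, config)), "regression")


# ---------------------------------------------------------------------------
# sklearn-style estimators
# ---------------------------------------------------------------------------

class SegmentationHC(BaseEstimator):
    """Segmentation-route HC estimator with a scikit-learn interface.

    ``fit(X, y)`` takes images ``X`` of shape (n, H, W) and binary head
    masks ``y`` of the same shape; ``predict(X, spacing=...)`` returns HC
    in mm (or in pixels when spacing is omitted).  Failed fits yield NaN.
    """

    def __init__(self, depth: int = 3, base_filters: int = 8,
                 input_size: tuple[int, int] = (64, 64), epochs: int = 20,
                 learning_rate: float = 1e-4, batch_size: int = 16,
                 threshold: float = 0.5, random_state: int = 0):
        self.depth = depth
        self.base_filters = base_filters
        self.input_size = input_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.threshold = threshold
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(learning_rate=self.learning_rate, batch_size=self.batch_size,
                           epochs=self.epochs, seed=self.random_state,
                           input_size=tuple(self.input_size))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3 or X.shape != y.shape:
            raise InvalidInputError("X and y must both be (n, H, W) with identical shapes")
        cfg = self._config()
        self.model_ = build_tiny_segnet(cfg, depth=self.depth, base_filters=self.base_filters)
        xin = preprocess_images(X, cfg.input_size)
        masks = np.stack([resize_mask(m, cfg.input_size) for m in y])
        self.loss_trace_ = train(self.model_, xin, masks, cfg, loss="dice")
        self.n_failed_ = 0
        return self

    def predict(self, X, spacing=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        n = X.shape[0]
        if spacing is None:
            spac = [PixelSpacing(1.0)] * n
        elif isinstance(spacing, PixelSpacing):
            spac = [spacing] * n
        elif np.isscalar(spacing):
            spac = [PixelSpacing(float(spacing))] * n
        else:
            spac = [s if isinstance(s, PixelSpacing) else PixelSpacing(float(s)) for s in spacing]
        out = np.full(n, np.nan)
        failed = 0
        for i in range(n):
            pred = estimate_hc_segmentation(X[i], self.model_, spac[i],
                                            image_id=str(i), threshold=self.threshold)
            if pred.success:
                out[i] = pred.hc_mm
            else:
                failed += 1
        self.n_failed_ = failed
        if failed:
            logger.warning("%d/%d segmentation-route predictions failed", failed, n)
        return out


class RegressionHC(BaseEstimator, RegressorMixin):
    """Regression-route HC estimator with a scikit-learn interface.

    ``fit(X, y)`` takes images (n, H, W) and reference HC in mm; targets
    are normalized by the maximum training HC.  ``predict(X)`` returns HC
    in mm.
    """

    def __init__(self, n_blocks: int = 3, base_filters: int = 8,
                 input_size: tuple[int, int] = (64, 64), epochs: int = 30,
                 learning_rate: float = 1e-4, batch_size: int = 16,
                 loss: str = "MAE", huber_delta: float = 1.0,
                 dropout_keep: float = 0.3, random_state: int = 0):
        self.n_blocks = n_blocks
        self.base_filters = base_filters
        self.input_size = input_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.loss = loss
        self.huber_delta = huber_delta
        self.dropout_keep = dropout_keep
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3 or X.shape[0] != y.shape[0]:
            raise InvalidInputError("X must be (n, H, W) and y (n,) HC values in mm")
        cfg = TrainConfig(learning_rate=self.learning_rate, batch_size=self.batch_size,
                          epochs=self.epochs, seed=self.random_state,
                          input_size=tuple(self.input_size),
                          dropout_keep=self.dropout_keep,
                          hc_norm_constant=float(y.max()))
        self.config_ = cfg
        self.model_ = build_tiny_regnet(cfg, n_blocks=self.n_blocks,
                                        base_filters=self.base_filters)
        xin = preprocess_images(X, cfg.input_size)
        t = normalize_hc(y, cfg)
        spec = RegressionLossSpec(kind=self.loss, delta=self.huber_delta)
        self.loss_trace_ = train(self.model_, xin, t, cfg, loss=spec)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        xin = preprocess_images(X, self.config_.input_size)
        out = self.model_.predict_scalar(xin)
        return np.asarray(denormalize_hc(out, self.config_))
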