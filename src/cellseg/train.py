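"""Loss, augmentation and the training loops.

The loss combines per-pixel cross-entropy H with a differentiable
(soft) Jaccard term: ``L = H - log J``.  J is computed per foreground
class from the predicted probabilities against the one-hot truth,

    J_c = (sum p_c y_c + eps) / (sum p_c + sum y_c - sum p_c y_c + eps)

with eps = 1 smoothing, averaged over the foreground classes present in
the truth (the dominant background class is excluded by default so it
cannot swamp the term).

Augmentation applies one random rotation+scale to image (bilinear) and
mask (nearest-neighbor, so class indices are preserved) plus a gray
value shift to the image only.  Optimization is Adam with the classical
moment decays (0.9, 0.999); fine-tuning runs the same loop with all
layers trainable at half the pretraining learning rate.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .io import DatasetSplit, TrainLogRow, write_train_log_csv
from .metrics import confusion, miou
from .unet import UNet, prepare_input, save_checkpoint, softmax

EPS_SMOOTH = 1.0
_P_FLOOR = 1e-12


@dataclass
class TrainConfig:
    batch_size: int = 4
    epochs: int = 200
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    rotation_deg: float = 30.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    gray_shift: float = 20.0
    augment: bool = True
    include_background_in_jaccard: bool = False
    seed: int = 0
    phase: str = "base"  # base | single | transfer

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        for b in (self.beta1, self.beta2):
            if not 0.0 < b < 1.0:
                raise ValueError("Adam betas must be in (0, 1)")

    @classmethod
    def transfer(cls, **overrides) -> "TrainConfig":
        kw = dict(learning_rate=5e-4, epochs=100, phase="transfer")
        kw.update(overrides)
        return cls(**kw)


@dataclass
class LossValue:
    total: float
    cross_entropy: float
    jaccard: float


# ---------------------------------------------------------------------------
# loss


def _one_hot(true: np.ndarray, num_classes: int) -> np.ndarray:
    return np.eye(num_classes, dtype=np.float32)[np.asarray(true, dtype=np.int64)]


def soft_jaccard(prob: np.ndarray, true: np.ndarray,
                 include_background: bool = False) -> float:
    """Soft Jaccard index of a (C, H, W) probability map against a class
    mask, averaged over the foreground classes present in the truth;
    1.0 when no such class exists."""
    prob = np.asarray(prob, dtype=np.float64)
    true = np.asarray(true)
    if prob.shape[1:] != true.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs true {true.shape}")
    j, _ = _soft_jaccard_batch(prob.transpose(1, 2, 0)[None], true[None],
                               include_background, with_grad=False)
    return j


def _soft_jaccard_batch(prob: np.ndarray, true: np.ndarray,
                        include_background: bool, with_grad: bool):
    """prob (B, H, W, C), true (B, H, W).  Returns (J, dJbar/dprob or None)."""
    num_classes = prob.shape[-1]
    y = _one_hot(true, num_classes)
    start = 0 if include_background else 1
    present = [c for c in range(start, num_classes) if (y[..., c] > 0).any()]
    if not present:
        return 1.0, (np.zeros_like(prob) if with_grad else None)
    jcs = []
    grad = np.zeros_like(prob) if with_grad else None
    for c in present:
        pc = prob[..., c]
        yc = y[..., c]
        inter = float((pc * yc).sum())
        union = float(pc.sum() + yc.sum() - inter)
        jc = (inter + EPS_SMOOTH) / (union + EPS_SMOOTH)
        jcs.append(jc)
        if with_grad:
            # d jc / d pc = (yc (union+eps) - (inter+eps)(1 - yc)) / (union+eps)^2
            grad[..., c] = (yc * (union + EPS_SMOOTH)
                            - (inter + EPS_SMOOTH) * (1.0 - yc)) / (union + EPS_SMOOTH) ** 2
    jbar = float(np.mean(jcs))
    if with_grad:
        grad /= len(jcs)
    return jbar, grad


def loss(prob: np.ndarray, true: np.ndarray,
         include_background: bool = False) -> LossValue:
    """Eq-style combined loss L = H - log J for a (C, H, W) probability
    map against a class mask."""
    prob = np.asarray(prob, dtype=np.float64)
    true = np.asarray(true)
    if prob.shape[1:] != true.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs true {true.shape}")
    p_true = np.take_along_axis(prob, true[None].astype(np.int64), axis=0)[0]
    h = float(-np.log(np.maximum(p_true, _P_FLOOR)).mean())
    j = soft_jaccard(prob, true, include_background)
    return LossValue(total=h - float(np.log(j)), cross_entropy=h, jaccard=j)


def loss_and_grad(logits: np.ndarray, true: np.ndarray,
                  include_background: bool = False):
    """Loss and its gradient w.r.t. the logits for a training batch.

    logits (B, H, W, C) float32, true (B, H, W) int.  Returns
    (LossValue, dlogits).
    """
    prob = softmax(np.asarray(logits, dtype=np.float64), axis=-1)
    true = np.asarray(true)
    y = _one_hot(true, prob.shape[-1])
    n_pix = true.size
    p_true = np.maximum((prob * y).sum(axis=-1), _P_FLOOR)
    h = float(-np.log(p_true).mean())
    j, djbar_dp = _soft_jaccard_batch(prob, true, include_background, with_grad=True)
    total = h - float(np.log(j))
    # dL/dp = dH/dp + d(-log J)/dp
    dl_dp = -(y / np.maximum(prob, _P_FLOOR)) / n_pix
    dl_dp += -djbar_dp / j
    # chain through the softmax: dlogits = p * (g - sum_c g_c p_c)
    inner = (dl_dp * prob).sum(axis=-1, keepdims=True)
    dlogits = (prob * (dl_dp - inner)).astype(np.float32)
    return LossValue(total=total, cross_entropy=h, jaccard=j), dlogits


# ---------------------------------------------------------------------------
# augmentation


def apply_rotation_scale(img: np.ndarray, mask: np.ndarray, theta: float,
                         scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotate by ``theta`` radians about the image center and scale
    isotropically, bilinear for the image and nearest-neighbor for the
    mask (class indices preserved), reflective out-of-bounds handling."""
    out_img = np.asarray(img)
    out_mask = np.asarray(mask)
    if theta == 0.0 and scale == 1.0:
        return out_img, out_mask
    # output coord -> input coord: rotate by -theta and scale by 1/scale
    cos, sin = np.cos(theta), np.sin(theta)
    mat = np.array([[cos, -sin], [sin, cos]], dtype=np.float64) / scale
    center = (np.asarray(img.shape, dtype=np.float64) - 1.0) / 2.0
    offset = center - mat @ center
    out_img = ndi.affine_transform(out_img.astype(np.float32), mat, offset=offset,
                                   order=1, mode="reflect")
    out_mask = ndi.affine_transform(out_mask, mat, offset=offset, order=0,
                                    mode="reflect")
    return out_img, out_mask


def augment(img: np.ndarray, mask: np.ndarray, config: TrainConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One random rotation + isotropic scale applied identically to
    image (bilinear) and mask (nearest); gray shift on the image only.
    Zero-range parameters give the identity transform."""
    theta = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg))
    lo, hi = config.scale_range
    s = rng.uniform(lo, hi)
    shift = rng.uniform(-config.gray_shift, config.gray_shift)
    out_img, out_mask = apply_rotation_scale(img, mask, theta, s)
    if shift != 0.0:
        out_img = out_img.astype(np.float32) + shift
    out_img = np.clip(np.rint(out_img), 0, 255).astype(np.uint8)
    return out_img, np.asarray(out_mask, dtype=np.uint8)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, model: UNet, config: TrainConfig):
        self.model = model
        self.lr = config.learning_rate
        self.b1, self.b2 = config.beta1, config.beta2
        self.eps = config.adam_eps
        self.t = 0
        layers = model.conv_layers()
        self.m = [np.zeros_like(l.W) for l in layers] + [np.zeros_like(l.b) for l in layers]
        self.v = [np.zeros_like(a) for a in self.m]

    def step(self) -> None:
        self.t += 1
        layers = self.model.conv_layers()
        params = [(l, "W", "gW") for l in layers] + [(l, "b", "gb") for l in layers]
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for i, (layer, pname, gname) in enumerate(params):
            g = getattr(layer, gname)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            update = self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            setattr(layer, pname, getattr(layer, pname) - update.astype(np.float32))


# ---------------------------------------------------------------------------
# training loops


@dataclass
class TrainResult:
    epochs: list[TrainLogRow]
    steps: list[LossValue]
    best_val_miou: float | None = None


def _as_pairs(data, num_classes: int):
    if isinstance(data, DatasetSplit):
        imgs, masks = data.load(num_classes)
        if masks is None:
            raise ValueError("training requires masks")
        return imgs, masks
    imgs, masks = zip(*data)
    return list(imgs), list(masks)


def evaluate_miou(model: UNet, pairs, num_classes: int) -> float:
    """Micro-averaged mIoU of the model over (image, mask) pairs."""
    from .unet import predict_batch

    imgs, masks = pairs
    preds = predict_batch(model, imgs)
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    for t, p in zip(masks, preds):
        cm += confusion(t, p, num_classes)
    return miou(cm)


def train(model: UNet, data, config: TrainConfig, val_data=None,
          log_path: str | Path | None = None,
          checkpoint_path: str | Path | None = None) -> TrainResult:
    """Minibatch training with augmentation, Adam, per-epoch validation
    mIoU and best-validation checkpointing.  Deterministic under
    ``config.seed``.

    ``data`` is a :class:`DatasetSplit` with masks or a sequence of
    (image, mask) pairs; masks hold class indices.
    """
    num_classes = model.config.num_classes
    imgs, masks = _as_pairs(data, num_classes)
    if not imgs:
        raise ValueError("empty training split")
    for im, ma in zip(imgs, masks):
        if im.shape[:2] != ma.shape:
            raise ValueError(f"image/mask shape mismatch: {im.shape} vs {ma.shape}")
    val_pairs = _as_pairs(val_data, num_classes) if val_data is not None else None

    rng = np.random.default_rng(config.seed)
    opt = Adam(model, config)
    result = TrainResult(epochs=[], steps=[])
    best = -np.inf
    best_weights = None
    n = len(imgs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xs, ys = [], []
            for i in idx:
                im, ma = imgs[i], masks[i]
                if config.augment:
                    im, ma = augment(im, ma, config, rng)
                xs.append(prepare_input(im, model.config.in_channels))
                ys.append(ma)
            x = np.stack(xs)
            y = np.stack(ys)
            model.zero_grad()
            logits = model.forward(x, train=True)
            lv, dlogits = loss_and_grad(logits, y,
                                        config.include_background_in_jaccard)
            model.backward(dlogits)
            opt.step()
            losses.append(lv)
            result.steps.append(lv)
        mean_loss = float(np.mean([l.total for l in losses]))
        mean_h = float(np.mean([l.cross_entropy for l in losses]))
        mean_j = float(np.exp(np.mean([np.log(l.jaccard) for l in losses])))
        val = None
        if val_pairs is not None:
            val = evaluate_miou(model, val_pairs, num_classes)
            if val > best:
                best = val
                best_weights = model.get_weights()
        result.epochs.append(TrainLogRow(epoch=epoch, loss=mean_loss,
                                         cross_entropy=mean_h, jaccard=mean_j,
                                         val_miou=val))
    if best_weights is not None:
        model.set_weights(best_weights)
        result.best_val_miou = float(best)
    if log_path is not None:
        write_train_log_csv(result.epochs, log_path)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return result


def finetune(model: UNet, small_data, config: TrainConfig | None = None,
             **kwargs) -> TrainResult:
    """Fine-tune a pretrained model on a small labeled mixed split.

    Same loop as :func:`train`, all layers trainable, transfer-phase
    defaults (half the pretraining learning rate).  Zero epochs leaves
    the weights untouched.
    """
    if config is None:
        config = TrainConfig.transfer()
    if config.epochs == 0:
        return TrainResult(epochs=[], steps=[])
    return train(model, small_data, config, **kwargs)
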