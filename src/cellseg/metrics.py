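"""Segmentation metrics: Jaccard, Dice, confusion matrix, mIoU, FWIoU.

Conventions: the confusion matrix ``p[i, j]`` counts pixels of true
class ``i`` predicted as class ``j``; per-class IoU is
``p_ii / (sum_j p_ij + sum_j p_ji - p_ii)``; mIoU averages per-class
IoUs, excluding classes absent from both truth and prediction (the 0/0
case) unless ``strict_k_plus_1`` restores the unconditional division by
``k + 1``; FWIoU weights per-class IoU by true-class pixel frequency.
Dataset-level metrics sum confusion matrices across images
(micro-average); a per-image macro-average is also provided.
"""

from __future__ import annotations

import numpy as np


class ShapeMismatchError(ValueError):
    pass


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")


def confusion(true: np.ndarray, pred: np.ndarray, num_classes: int) -> np.ndarray:
    """Exact per-pixel tally: ``out[i, j]`` = pixels of true class i
    predicted as class j."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    _check_same_shape(true, pred)
    t = true.ravel().astype(np.int64)
    p = pred.ravel().astype(np.int64)
    if t.size and (t.max() >= num_classes or p.max() >= num_classes or
                   t.min() < 0 or p.min() < 0):
        raise ValueError(f"mask values outside 0..{num_classes - 1}")
    cm = np.bincount(t * num_classes + p, minlength=num_classes * num_classes)
    return cm.reshape(num_classes, num_classes)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B| of two binary masks; 1.0 when both
    are empty."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    _check_same_shape(a, b)
    inter = int(np.logical_and(a, b).sum())
    union = int(a.sum()) + int(b.sum()) - inter
    return 1.0 if union == 0 else inter / union


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 1.0 when both are empty.
    Related to Jaccard by D = 2J / (1 + J)."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    _check_same_shape(a, b)
    inter = int(np.logical_and(a, b).sum())
    denom = int(a.sum()) + int(b.sum())
    return 1.0 if denom == 0 else 2.0 * inter / denom


def per_class_iou(cm: np.ndarray) -> np.ndarray:
    """Per-class IoU from a confusion matrix; NaN where the class is
    absent from both truth and prediction."""
    cm = np.asarray(cm, dtype=np.float64)
    tp = np.diag(cm)
    denom = cm.sum(axis=1) + cm.sum(axis=0) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(denom > 0, tp / np.where(denom > 0, denom, 1.0), np.nan)
    return iou


def miou(cm: np.ndarray, strict_k_plus_1: bool = False) -> float:
    """Mean IoU over classes.

    Classes with an empty denominator (absent from truth and prediction)
    are excluded from the mean; ``strict_k_plus_1=True`` instead counts
    them as 0 and divides by the full number of classes.
    """
    cm = np.asarray(cm, dtype=np.float64)
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    iou = per_class_iou(cm)
    if strict_k_plus_1:
        return float(np.nan_to_num(iou, nan=0.0).sum() / cm.shape[0])
    valid = ~np.isnan(iou)
    return float(iou[valid].mean())


def fwiou(cm: np.ndarray) -> float:
    """Frequency-weighted IoU: per-class IoUs weighted by true-class
    pixel frequency.  Classes with zero frequency contribute nothing."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if cm.size == 0 or total == 0:
        raise ValueError("empty confusion matrix")
    iou = per_class_iou(cm)
    freq = cm.sum(axis=1) / total
    present = freq > 0
    return float((freq[present] * iou[present]).sum())


def dice_multiclass(true: np.ndarray, pred: np.ndarray, num_classes: int) -> float:
    """Unweighted mean of per-foreground-class Dice scores; classes
    absent from both masks are excluded (1.0 if none are present)."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    _check_same_shape(true, pred)
    scores = []
    for c in range(1, num_classes):
        a = true == c
        b = pred == c
        if not a.any() and not b.any():
            continue
        scores.append(dice(a, b))
    return 1.0 if not scores else float(np.mean(scores))


def evaluate_split(trues: list[np.ndarray], preds: list[np.ndarray],
                   num_classes: int, macro: bool = False) -> dict:
    """Dataset-level metrics.

    Micro (default): confusion matrices summed over images before
    computing mIoU / FWIoU; Dice is computed from pooled pixel counts
    per class.  ``macro=True`` averages per-image metrics instead.
    """
    if len(trues) != len(preds) or not trues:
        raise ValueError("need equal, nonzero numbers of truth and prediction masks")
    if macro:
        ms, fs, ds = [], [], []
        for t, p in zip(trues, preds):
            cm = confusion(t, p, num_classes)
            ms.append(miou(cm))
            fs.append(fwiou(cm))
            ds.append(dice_multiclass(t, p, num_classes))
        return {"miou": float(np.mean(ms)), "fwiou": float(np.mean(fs)),
                "dice": float(np.mean(ds)), "n_images": len(trues)}
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    inter = np.zeros(num_classes, dtype=np.int64)
    sizes = np.zeros(num_classes, dtype=np.int64)
    for t, p in zip(trues, preds):
        cm += confusion(t, p, num_classes)
        for c in range(1, num_classes):
            inter[c] += int(np.logical_and(t == c, p == c).sum())
            sizes[c] += int((t == c).sum()) + int((p == c).sum())
    dices = [2.0 * inter[c] / sizes[c] for c in range(1, num_classes) if sizes[c] > 0]
    return {
        "miou": miou(cm),
        "fwiou": fwiou(cm),
        "dice": 1.0 if not dices else float(np.mean(dices)),
        "confusion": cm,
        "n_images": len(trues),
    }
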