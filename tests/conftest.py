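"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive per-pixel Python loops (or direct
set arithmetic) so they share no code path with the implementation
under test.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# oracles: morphology


def minmax_filter_oracle(img: np.ndarray, k: int, mode: str) -> np.ndarray:
    """Window min/max with replicate borders, one pixel at a time."""
    h, w = img.shape
    r = k // 2
    out = np.empty_like(img)
    pick = min if mode == "min" else max
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    vals.append(img[ii, jj])
            out[i, j] = pick(vals)
    return out


# ---------------------------------------------------------------------------
# oracles: Gaussian-weighted local threshold


def gaussian_weights_oracle(size: int, sigma: float) -> list[list[float]]:
    r = size // 2
    w = [[math.exp(-(di * di + dj * dj) / (2.0 * sigma * sigma))
          for dj in range(-r, r + 1)] for di in range(-r, r + 1)]
    total = sum(sum(row) for row in w)
    return [[v / total for v in row] for row in w]


def adaptive_threshold_oracle(img: np.ndarray, window: int, C: float,
                              polarity: str, sigma: float) -> np.ndarray:
    """Per-pixel Gaussian-weighted mean threshold, reflective borders."""
    h, w = img.shape
    r = window // 2
    weights = gaussian_weights_oracle(window, sigma)

    def reflect(i, n):
        # scipy 'reflect' mode: (d c b a | a b c d | d c b a)
        while i < 0 or i >= n:
            if i < 0:
                i = -i - 1
            else:
                i = 2 * n - 1 - i
        return i

    out = np.zeros((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            t = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii = reflect(i + di, h)
                    jj = reflect(j + dj, w)
                    t += weights[di + r][dj + r] * float(img[ii, jj])
            t -= C
            x = float(img[i, j])
            fg = (x < t) if polarity == "dark" else (x > t)
            out[i, j] = 1 if fg else 0
    return out


# ---------------------------------------------------------------------------
# oracles: connected components (flood fill)


def flood_fill_count_oracle(mask: np.ndarray) -> int:
    """8-connected component count by explicit BFS flood fill."""
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    count = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < h and 0 <= cc < w and mask[rr, cc]
                                    and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return count


def flood_fill_area_oracle(mask: np.ndarray) -> list[int]:
    """Areas of the 8-connected components, in discovery (raster) order."""
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    areas = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                area = 0
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    area += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < h and 0 <= cc < w and mask[rr, cc]
                                    and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                areas.append(area)
    return areas


# ---------------------------------------------------------------------------
# oracles: metrics (nested loops and direct set arithmetic)


def confusion_oracle(true: np.ndarray, pred: np.ndarray, k: int) -> np.ndarray:
    cm = np.zeros((k, k), dtype=np.int64)
    for i in range(true.shape[0]):
        for j in range(true.shape[1]):
            cm[int(true[i, j]), int(pred[i, j])] += 1
    return cm


def jaccard_oracle(a: np.ndarray, b: np.ndarray) -> float:
    sa = {(i, j) for i in range(a.shape[0]) for j in range(a.shape[1]) if a[i, j]}
    sb = {(i, j) for i in range(b.shape[0]) for j in range(b.shape[1]) if b[i, j]}
    union = sa | sb
    return 1.0 if not union else len(sa & sb) / len(union)


def dice_oracle(a: np.ndarray, b: np.ndarray) -> float:
    sa = {(i, j) for i in range(a.shape[0]) for j in range(a.shape[1]) if a[i, j]}
    sb = {(i, j) for i in range(b.shape[0]) for j in range(b.shape[1]) if b[i, j]}
    if not sa and not sb:
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def miou_oracle(cm) -> float:
    k = len(cm)
    ious = []
    for i in range(k):
        tp = cm[i][i]
        denom = sum(cm[i][j] for j in range(k)) + sum(cm[j][i] for j in range(k)) - tp
        if denom > 0:
            ious.append(tp / denom)
    return sum(ious) / len(ious)


def fwiou_oracle(cm) -> float:
    k = len(cm)
    total = sum(cm[i][j] for i in range(k) for j in range(k))
    acc = 0.0
    for i in range(k):
        freq = sum(cm[i][j] for j in range(k)) / total
        tp = cm[i][i]
        denom = sum(cm[i][j] for j in range(k)) + sum(cm[j][i] for j in range(k)) - tp
        if denom > 0:
            acc += freq * (tp / denom)
    return acc


# ---------------------------------------------------------------------------
# oracle: combined loss by direct formula re-evaluation


def loss_oracle(prob: np.ndarray, true: np.ndarray, eps: float = 1.0):
    """L = H - log J evaluated with plain Python sums.  prob is (C, H, W)."""
    C, H, W = prob.shape
    h_sum = 0.0
    for i in range(H):
        for j in range(W):
            h_sum += -math.log(prob[int(true[i, j]), i, j])
    h_term = h_sum / (H * W)
    jcs = []
    for c in range(1, C):
        if not (true == c).any():
            continue
        inter = sum(prob[c, i, j] for i in range(H) for j in range(W)
                    if true[i, j] == c)
        psum = sum(prob[c, i, j] for i in range(H) for j in range(W))
        ysum = int((true == c).sum())
        jcs.append((inter + eps) / (psum + ysum - inter + eps))
    j_term = 1.0 if not jcs else sum(jcs) / len(jcs)
    return h_term - math.log(j_term), h_term, j_term


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_binary_masks(rng):
    """A batch of random 16x16 binary masks of varying density."""
    masks = []
    for density in (0.1, 0.3, 0.5, 0.7):
        for _ in range(25):
            masks.append((rng.random((16, 16)) < density).astype(np.uint8))
    return masks
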