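"""Automatic training-label generation for single-kind cell images.

Pipeline: Gaussian smoothing -> adaptive (Gaussian-weighted local mean)
thresholding -> border-following contour extraction -> small-area
removal -> optional morphological opening (to separate adhesive cells
and drop thin impurities) -> contour filling.  The filled mask, tagged
with the image's single class value, is the training label.

Numerical conventions (fixed and documented, the literature leaves them
open): reflective borders for convolution and thresholding, replicate
borders for morphology; a pixel exactly at its local threshold is
background (strict inequality); contour areas are *filled* areas, and
filling closes interior holes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk as _disk

from .io import as_gray_image


class ConfigError(ValueError):
    pass


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# kernels


def gaussian_kernel_1d(size: int, sigma: float) -> np.ndarray:
    if size < 1 or size % 2 == 0:
        raise ConfigError(f"kernel size must be odd and >= 1, got {size}")
    if sigma <= 0:
        raise ConfigError(f"sigma must be > 0, got {sigma}")
    d = np.arange(size) - size // 2
    k = np.exp(-(d.astype(np.float64) ** 2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Separable 2-D Gaussian kernel, normalized to sum 1."""
    k = gaussian_kernel_1d(size, sigma)
    return np.outer(k, k)


def default_threshold_sigma(window: int) -> float:
    """Sigma used for the Gaussian threshold window when none is given:
    ``0.3 * ((window - 1) * 0.5 - 1) + 0.8`` (the classical choice tying
    kernel support to window size; gives 0.8 for a 3x3 window)."""
    return 0.3 * ((window - 1) * 0.5 - 1.0) + 0.8


# ---------------------------------------------------------------------------
# smoothing and thresholding


def gaussian_smooth(img: np.ndarray, size: int = 3, sigma: float = 0.8) -> np.ndarray:
    """Gaussian filtering with a normalized ``size x size`` kernel,
    reflective borders, rounded back to uint8."""
    img = as_gray_image(img)
    k = gaussian_kernel(size, sigma)
    out = ndi.convolve(img.astype(np.float64), k, mode="reflect")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def adaptive_threshold(img: np.ndarray, window: int = 3, C: float = 2.0,
                       polarity: str = "dark", sigma: float | None = None) -> np.ndarray:
    """Per-pixel binarization against a Gaussian-weighted local mean.

    The threshold at each pixel is the Gaussian-weighted mean of the
    ``window x window`` neighborhood (reflective borders) minus ``C``.
    With ``polarity='dark'`` a pixel is foreground iff it is strictly
    darker than its threshold; ``'light'`` flips the comparison.  Ties
    are background.  Returns a binary uint8 mask (0/1).
    """
    img = as_gray_image(img)
    if window < 3 or window % 2 == 0:
        raise ConfigError(f"window must be odd and >= 3, got {window}")
    if polarity not in ("dark", "light"):
        raise ConfigError(f"polarity must be 'dark' or 'light', got {polarity!r}")
    if sigma is None:
        sigma = default_threshold_sigma(window)
    k = gaussian_kernel(window, sigma)
    t = ndi.convolve(img.astype(np.float64), k, mode="reflect") - C
    x = img.astype(np.float64)
    fg = (x < t) if polarity == "dark" else (x > t)
    return fg.astype(np.uint8)


# ---------------------------------------------------------------------------
# grayscale morphology (min / max filters)


def _footprint(kernel: int | np.ndarray) -> np.ndarray:
    if np.isscalar(kernel):
        k = int(kernel)
        if k < 1 or k % 2 == 0:
            raise ConfigError(f"kernel size must be odd and >= 1, got {k}")
        return np.ones((k, k), dtype=bool)
    fp = np.asarray(kernel).astype(bool)
    if fp.ndim != 2 or fp.shape[0] % 2 == 0 or fp.shape[1] % 2 == 0:
        raise ConfigError(f"kernel must be 2-D with odd dimensions, got {fp.shape}")
    return fp


def disk_footprint(radius: int) -> np.ndarray:
    """Disk-shaped structuring element (odd square bounding box)."""
    return _disk(radius).astype(bool)


def erode(img: np.ndarray, kernel: int | np.ndarray = 3) -> np.ndarray:
    """Minimum filter over the kernel support, anchor at the kernel
    center, replicate border padding."""
    fp = _footprint(kernel)
    return ndi.grey_erosion(np.asarray(img), footprint=fp, mode="nearest").astype(
        np.asarray(img).dtype
    )


def dilate(img: np.ndarray, kernel: int | np.ndarray = 3) -> np.ndarray:
    """Maximum filter over the kernel support (mirror of :func:`erode`)."""
    fp = _footprint(kernel)
    return ndi.grey_dilation(np.asarray(img), footprint=fp, mode="nearest").astype(
        np.asarray(img).dtype
    )


def open_morph(mask: np.ndarray, kernel: int | np.ndarray = 3) -> np.ndarray:
    """Erosion followed by dilation; splits thin bridges between adhesive
    cells and removes structures thinner than the kernel."""
    return dilate(erode(mask, kernel), kernel)


# ---------------------------------------------------------------------------
# contours

_EIGHT = np.ones((3, 3), dtype=bool)

# clockwise Moore neighborhood starting from the west neighbor
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


@dataclass
class Contour:
    """Closed outer boundary of one 8-connected foreground component.

    ``points`` is the ordered (row, col) boundary sequence from
    Moore-neighbor tracing; consecutive points are 8-adjacent and the
    first and last points are adjacent when closed.  ``filled_area`` is
    the pixel count of the component with interior holes closed.
    """

    points: np.ndarray
    closed: bool
    filled_area: int


def _trace_boundary(comp: np.ndarray, start: tuple[int, int]) -> np.ndarray:
    """Moore-neighbor boundary tracing with Jacob's stopping criterion.

    ``start`` must be the first foreground pixel of ``comp`` in raster
    order (so its west neighbor is background).
    """
    h, w = comp.shape

    def fg(r, c):
        return 0 <= r < h and 0 <= c < w and comp[r, c]

    points = [start]
    cur = start
    back_dir = 0  # direction from cur to its backtrack pixel (west initially)
    # single-pixel component: no foreground neighbor at all
    if not any(fg(start[0] + dr, start[1] + dc) for dr, dc in _MOORE):
        return np.array(points, dtype=np.intp)

    def step(cur, back_dir):
        for i in range(1, 9):
            d = (back_dir + i) % 8
            nr, nc = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if fg(nr, nc):
                prev = (back_dir + i - 1) % 8
                # backtrack for the next scan: the background neighbor
                # examined just before (nr, nc), seen from (nr, nc)
                br = cur[0] + _MOORE[prev][0] - nr
                bc = cur[1] + _MOORE[prev][1] - nc
                return (nr, nc), _MOORE.index((br, bc))
        raise AssertionError("unreachable: component has a foreground neighbor")

    # the tracing map is deterministic, so the boundary loop is the cycle
    # through the state reached after the first move; trace until that
    # state recurs (Jacob's stopping criterion)
    first_state = step(cur, back_dir)
    cur, back_dir = first_state
    points.append(cur)
    limit = 4 * int(comp.sum()) + 8
    for _ in range(limit):
        cur, back_dir = step(cur, back_dir)
        if (cur, back_dir) == first_state:
            break
        points.append(cur)
    else:  # pragma: no cover - safety net
        raise RuntimeError("boundary tracing did not terminate")
    if len(points) > 1 and points[-1] == points[0]:
        points.pop()
    return np.array(points, dtype=np.intp)


def find_contours(mask: np.ndarray) -> list[Contour]:
    """Outermost closed borders of the 8-connected foreground components.

    Holes are ignored (no parent borders).  Contours are ordered by the
    raster position of their top-left-most starting pixel.
    """
    mask = np.asarray(mask) > 0
    labels, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return []
    objects = ndi.find_objects(labels)
    entries = []
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        comp = labels[sl] == lab
        rows, cols = np.nonzero(comp)
        first = int(np.argmin(rows * comp.shape[1] + cols))
        start_local = (int(rows[first]), int(cols[first]))
        pts = _trace_boundary(comp, start_local)
        pts = pts + np.array([sl[0].start, sl[1].start])
        filled = int(ndi.binary_fill_holes(comp).sum())
        key = (start_local[0] + sl[0].start, start_local[1] + sl[1].start)
        entries.append((key, Contour(points=pts, closed=True, filled_area=filled)))
    entries.sort(key=lambda e: e[0])
    return [c for _, c in entries]


def filter_small(contours: list[Contour], min_area: float) -> list[Contour]:
    """Drop contours whose filled area is below ``min_area`` (impurities,
    broken cells); order preserved."""
    if min_area < 0:
        raise ConfigError(f"min_area must be >= 0, got {min_area}")
    return [c for c in contours if c.filled_area >= min_area]


def fill_contours(contours: list[Contour], shape: tuple[int, int],
                  class_value: int = 1) -> np.ndarray:
    """Rasterize contours as filled regions of ``class_value``.

    The boundary curve is drawn and everything it encloses is filled, so
    ring-shaped components come back as solid discs (holes closed).
    """
    if class_value < 1:
        raise ConfigError(f"class_value must be >= 1, got {class_value}")
    out = np.zeros(shape, dtype=bool)
    for c in contours:
        pts = np.asarray(c.points)
        if pts.size == 0:
            continue
        if (pts < 0).any() or (pts[:, 0] >= shape[0]).any() or (pts[:, 1] >= shape[1]).any():
            raise GeometryError("contour point outside the target shape")
        # fill each contour independently (inside its bounding box) so a
        # pocket enclosed only jointly by several contours stays open
        r0, c0 = pts.min(axis=0)
        r1, c1 = pts.max(axis=0) + 1
        canvas = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        canvas[pts[:, 0] - r0, pts[:, 1] - c0] = True
        out[r0:r1, c0:c1] |= ndi.binary_fill_holes(canvas)
    return (out * class_value).astype(np.uint8)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class AutolabelConfig:
    """Parameters of the auto-labeling pipeline.

    Defaults follow the classical recipe: 3x3 Gaussian with sigma 0.8 per
    axis, a 3x3 threshold window, offset C=2, cells darker than
    background, 3x3 square morphology kernel.  The synthetic presets
    widen the window to ``2*r_max + 1`` and use disk footprints sized
    from the cell geometry (see :func:`preset_for_kind`).
    """

    gaussian_size: int = 3
    gaussian_sigma: float = 0.8
    window: int = 3
    offset: float = 2.0
    polarity: str = "dark"
    threshold_sigma: float | None = None
    min_area: float = 0.0
    morphology: bool = False
    morph_kernel: int | np.ndarray = 3

    def __post_init__(self) -> None:
        if self.gaussian_size % 2 == 0 or self.window % 2 == 0:
            raise ConfigError("gaussian_size and window must be odd")
        if self.gaussian_sigma <= 0:
            raise ConfigError("gaussian_sigma must be > 0")
        if self.min_area < 0:
            raise ConfigError("min_area must be >= 0")


def preset_for_kind(synth_cfg, kind: str) -> AutolabelConfig:
    """Robust auto-label preset for synthetic scenes of one kind.

    Window = ``2 * r_max + 1`` of the kind's cell class; min area = half
    the smallest true cell area; morphology uses a small disk sized to
    remove thin structures only: debris fibers (~2-3 px wide) in either
    kind, plus the threshold bridges between adhesive macrophages
    (contact gap + smoothing support, <= 5 px thick), while leaving
    cell bodies (radius >= 3 px) intact.
    """
    if kind == "rbc":
        rmin, rmax = synth_cfg.rbc_radius
        morph = disk_footprint(2)
    elif kind == "macrophage":
        rmin, rmax = synth_cfg.mac_radius
        morph = disk_footprint(3)
    else:
        raise ValueError(f"no single-kind preset for {kind!r}")
    window = 2 * int(np.ceil(rmax)) + 1
    if window % 2 == 0:
        window += 1
    return AutolabelConfig(
        window=window,
        offset=2.0,
        min_area=np.pi * rmin**2 / 2.0,
        morphology=True,
        morph_kernel=morph,
    )


def autolabel_image(img: np.ndarray, config: AutolabelConfig,
                    class_value: int = 1) -> np.ndarray:
    """Run the full label-generation pipeline on a single-kind image.

    Returns a ClassMask with foreground set to ``class_value``.
    """
    smoothed = gaussian_smooth(img, config.gaussian_size, config.gaussian_sigma)
    binary = adaptive_threshold(smoothed, config.window, config.offset,
                                config.polarity, sigma=config.threshold_sigma)
    contours = filter_small(find_contours(binary), config.min_area)
    filled = fill_contours(contours, img.shape, 1)
    if config.morphology:
        opened = open_morph(filled, config.morph_kernel)
        contours = filter_small(find_contours(opened), config.min_area)
        filled = fill_contours(contours, img.shape, 1)
    return (filled * class_value).astype(np.uint8)
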