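"""Image, mask and dataset I/O.

Images are plain 2-D ``uint8`` numpy arrays (grayscale, values 0-255);
class masks are 2-D ``uint8`` arrays whose values are class indices
``{0, ..., k}`` with 0 = background, 1 = RBC, 2 = macrophage.  Masks are
stored as raw 8-bit grayscale PNG (pixel value == class index, no
palette), which makes round-trips bit-exact and diffs trivial.

Coordinates are (row, col), 0-based, origin at the top-left corner,
everywhere in this package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

log = logging.getLogger("cellseg")

#: Rec. 601 luma weights used for RGB -> grayscale conversion.
REC601 = (0.299, 0.587, 0.114)


class FormatError(ValueError):
    """Raised when a file cannot be decoded as an 8-bit image."""


class MaskValueError(ValueError):
    """Raised when a mask contains values outside {0, ..., k}."""


def as_gray_image(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to a uint8 grayscale image."""
    arr = np.asarray(arr)
    if arr.ndim != 2 or arr.size == 0:
        raise FormatError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return arr


def validate_mask(mask: np.ndarray, num_classes: int) -> np.ndarray:
    """Check that ``mask`` is 2-D uint8 with values in {0, ..., num_classes-1}."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise MaskValueError(f"expected a 2-D mask, got shape {mask.shape}")
    if mask.dtype != np.uint8:
        mask = mask.astype(np.uint8, casting="safe") if mask.dtype == np.bool_ else mask
    bad = (np.asarray(mask) >= num_classes) | (np.asarray(mask) < 0)
    if bad.any():
        offending = int(np.asarray(mask)[bad].flat[0])
        raise MaskValueError(
            f"mask value {offending} outside valid classes 0..{num_classes - 1}"
        )
    return np.asarray(mask, dtype=np.uint8)


def read_image(path: str | Path, luma: Sequence[float] = REC601) -> np.ndarray:
    """Read a PNG/TIFF image as a uint8 grayscale array.

    RGB(A) inputs are converted to single-channel luminance with the
    given weights (Rec. 601 by default) and rounded; values are clamped
    to [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode == "L":
                arr = np.asarray(im)
            elif im.mode in ("P", "RGBA", "LA", "I;16", "I", "F", "1"):
                arr = np.asarray(im.convert("RGB"), dtype=np.float64)
                arr = arr @ np.asarray(luma, dtype=np.float64)
            elif im.mode == "RGB":
                arr = np.asarray(im, dtype=np.float64) @ np.asarray(luma, dtype=np.float64)
            else:
                raise FormatError(f"unsupported image mode {im.mode!r} in {path}")
    except FormatError:
        raise
    except Exception as exc:  # PIL raises various decode errors
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    return as_gray_image(arr)


def write_image(img: np.ndarray, path: str | Path) -> Path:
    """Write a grayscale image as 8-bit PNG; round-trips bit-exactly."""
    path = Path(path)
    Image.fromarray(as_gray_image(img), mode="L").save(path)
    return path


def read_mask(path: str | Path, num_classes: int = 3) -> np.ndarray:
    """Read an 8-bit class mask PNG and validate its values."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        im.load()
        if im.mode == "P":
            # paletted masks: the index is the class value
            arr = np.asarray(im)
        elif im.mode == "L":
            arr = np.asarray(im)
        else:
            raise FormatError(f"mask {path} must be 8-bit gray/indexed PNG, got {im.mode!r}")
    return validate_mask(arr, num_classes)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a class mask as raw 8-bit grayscale PNG (class index verbatim)."""
    mask = np.asarray(mask, dtype=np.uint8)
    if mask.ndim != 2:
        raise MaskValueError(f"expected 2-D mask, got shape {mask.shape}")
    path = Path(path)
    Image.fromarray(mask, mode="L").save(path)
    return path


@dataclass
class DatasetSplit:
    """A list of image paths with optional one-to-one mask paths."""

    images: list[Path]
    masks: list[Path] | None = None
    role: str = "train"

    def __post_init__(self) -> None:
        self.images = [Path(p) for p in self.images]
        if self.masks is not None:
            self.masks = [Path(p) for p in self.masks]
            if len(self.masks) != len(self.images):
                raise ValueError(
                    f"{len(self.images)} images but {len(self.masks)} masks"
                )

    def __len__(self) -> int:
        return len(self.images)

    def load(self, num_classes: int = 3) -> tuple[list[np.ndarray], list[np.ndarray] | None]:
        imgs = [read_image(p) for p in self.images]
        if self.masks is None:
            return imgs, None
        masks = [read_mask(p, num_classes) for p in self.masks]
        for i, (im, ma) in enumerate(zip(imgs, masks)):
            if im.shape != ma.shape:
                raise ValueError(f"shape mismatch at index {i}: {im.shape} vs {ma.shape}")
        return imgs, masks


def discover_split(
    root: str | Path,
    kind: str,
    role: str = "train",
    masks_dir: str = "masks",
    require_masks: bool = True,
) -> DatasetSplit:
    """Discover ``<root>/<kind>/{images,masks}/*.png`` deterministically.

    File lists are lexicographically sorted so splits are reproducible.
    """
    root = Path(root)
    img_dir = root / kind / "images"
    if not img_dir.is_dir():
        raise FileNotFoundError(img_dir)
    images = sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.tif")) + sorted(
        img_dir.glob("*.tiff")
    )
    mdir = root / kind / masks_dir
    masks: list[Path] | None = None
    if mdir.is_dir():
        masks = [mdir / (p.stem + ".png") for p in images]
        missing = [m for m in masks if not m.exists()]
        if missing:
            raise FileNotFoundError(f"missing masks: {missing[:3]}...")
    elif require_masks:
        raise FileNotFoundError(mdir)
    return DatasetSplit(images=images, masks=masks, role=role)


def save_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def load_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass
class TrainLogRow:
    epoch: int
    loss: float
    cross_entropy: float
    jaccard: float
    val_miou: float | None = None


def write_train_log_csv(rows: list[TrainLogRow], path: str | Path) -> Path:
    import csv

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "loss", "H", "J", "val_mIoU"])
        for r in rows:
            w.writerow([r.epoch, f"{r.loss:.6f}", f"{r.cross_entropy:.6f}",
                        f"{r.jaccard:.6f}", "" if r.val_miou is None else f"{r.val_miou:.6f}"])
    return path
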