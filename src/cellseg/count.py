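"""Segmentation-driven cell counting.

Per class value, 8-connected components of the predicted mask are
extracted; components smaller than a per-class minimum area are treated
as false positives and dropped; each surviving component counts as one
cell.  An optional split-large policy divides unusually large
components (merged cells) by a typical single-cell area instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class ComponentStats:
    """One connected component of one class."""

    component_id: int
    cls: int
    area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    touches_border: bool


@dataclass
class CountReport:
    counts: dict[int, int]
    min_area: dict[int, float]
    components: list[ComponentStats]
    split_large: bool
    typical_area: dict[int, float] | None = None

    def accuracy(self, truth_counts: dict[int, int]) -> dict[int, float | None]:
        return count_accuracy(self, truth_counts)


def components(mask: np.ndarray) -> list[ComponentStats]:
    """8-connected components per class value, ids in raster order of
    each component's first pixel, classes in ascending order."""
    mask = np.asarray(mask)
    h, w = mask.shape
    out: list[ComponentStats] = []
    next_id = 0
    for cls in sorted(int(v) for v in np.unique(mask) if v != 0):
        labels, n = ndi.label(mask == cls, structure=_EIGHT)
        if n == 0:
            continue
        objects = ndi.find_objects(labels)
        entries = []
        for lab in range(1, n + 1):
            sl = objects[lab - 1]
            comp = labels[sl] == lab
            rows, cols = np.nonzero(comp)
            first = int(np.argmin(rows * comp.shape[1] + cols))
            key = (int(rows[first]) + sl[0].start, int(cols[first]) + sl[1].start)
            area = int(comp.sum())
            centroid = (float(rows.mean()) + sl[0].start, float(cols.mean()) + sl[1].start)
            bbox = (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)
            touches = (bbox[0] == 0 or bbox[1] == 0 or bbox[2] == h or bbox[3] == w)
            entries.append((key, cls, area, centroid, bbox, touches))
        entries.sort(key=lambda e: e[0])
        for key, c, area, centroid, bbox, touches in entries:
            out.append(ComponentStats(component_id=next_id, cls=c, area=area,
                                      centroid=centroid, bbox=bbox,
                                      touches_border=touches))
            next_id += 1
    return out


def count_cells(mask: np.ndarray, min_area_per_class: dict[int, float] | float = 0.0,
                split_large: bool = False,
                typical_area_per_class: dict[int, float] | None = None,
                num_classes: int | None = None) -> CountReport:
    """Count cells per class from a predicted class mask.

    Components with area below the class's ``min_area`` are excluded as
    false positives.  With ``split_large`` on, a component larger than
    1.5x the class's typical area counts as ``round(area / typical)``
    cells (never less than 1).
    """
    mask = np.asarray(mask)
    if num_classes is not None:
        bad = mask[mask >= num_classes]
        if bad.size:
            raise ValueError(f"unknown class value {int(bad.flat[0])} in mask")
    comps = components(mask)
    classes = sorted({c.cls for c in comps})

    def min_area_for(cls: int) -> float:
        if isinstance(min_area_per_class, dict):
            return float(min_area_per_class.get(cls, 0.0))
        return float(min_area_per_class)

    for cls in classes:
        if min_area_for(cls) < 0:
            raise ValueError("min_area must be >= 0")
    if split_large and typical_area_per_class is None:
        raise ValueError("split_large requires typical_area_per_class")

    kept: list[ComponentStats] = []
    counts: dict[int, int] = {c: 0 for c in classes}
    for comp in comps:
        if comp.area < min_area_for(comp.cls):
            continue
        kept.append(comp)
        if split_large:
            typical = float(typical_area_per_class[comp.cls])
            if comp.area > 1.5 * typical:
                counts[comp.cls] += max(1, int(np.rint(comp.area / typical)))
                continue
        counts[comp.cls] += 1
    return CountReport(
        counts=counts,
        min_area={c: min_area_for(c) for c in classes},
        components=kept,
        split_large=split_large,
        typical_area=typical_area_per_class,
    )


def count_accuracy(report: CountReport, truth_counts: dict[int, int]) -> dict[int, float | None]:
    """Predicted/truth per class, as a percentage (e.g. 99.01 for
    401/405); ``None`` (n/a) where truth is zero."""
    out: dict[int, float | None] = {}
    for cls, truth in truth_counts.items():
        if truth < 0:
            raise ValueError("truth counts must be >= 0")
        pred = report.counts.get(cls, 0)
        out[cls] = None if truth == 0 else 100.0 * pred / truth
    return out


def report_to_dict(report: CountReport,
                   accuracy: dict[int, float | None] | None = None) -> dict:
    """JSON-serializable form of a count report."""
    d = {
        "counts": {str(k): v for k, v in report.counts.items()},
        "min_area": {str(k): v for k, v in report.min_area.items()},
        "split_large": report.split_large,
        "components": [
            {
                "id": c.component_id,
                "class": c.cls,
                "area": c.area,
                "centroid": list(c.centroid),
                "bbox": list(c.bbox),
                "touches_border": c.touches_border,
            }
            for c in report.components
        ],
    }
    if accuracy is not None:
        d["accuracy_pct"] = {
            str(k): (None if v is None else round(v, 2)) for k, v in accuracy.items()
        }
    return d
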