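"""Seeded generator of synthetic bright-field cell scenes.

Emulates the statistical structure of mixed RBC / macrophage microscopy
crops: small near-circular RBC-like cells, macrophage-like cells ~2.5x
larger, occasional adhesive macrophage pairs, occasional thin debris
fibers (impurities from the culture solution, drawn on the image but
absent from the truth mask), additive Gaussian sensor noise, and a
smooth linear illumination gradient.

Every scene carries its ground-truth class mask and true per-class cell
counts, so each downstream stage (auto-labeling, training, counting) is
testable without real data.  Generation is bit-exact reproducible from
``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import polygon as _draw_polygon

from .io import save_json, write_image, write_mask, DatasetSplit

KINDS = ("rbc", "macrophage", "mixed")

#: center distance of an adhesive pair, as a fraction of the sum of the
#: two cells' nominal (free) radii.  Adhering cells flatten against each
#: other instead of interpenetrating: the drawn bodies stay
#: ``ADHESION_GAP`` pixels apart, joined by a thin strip of cell
#: material (the adhesion interface, drawn in both image and truth
#: mask).  The pair therefore appears as one connected dumbbell-shaped
#: region whose thin bridge morphological opening can remove, splitting
#: the pair back into two cell bodies.
ADHESION_DISTANCE_FACTOR = 0.97
ADHESION_GAP = 3.5
#: contact interface half-thickness along the pair axis, px
ADHESION_INTERFACE_THICKNESS = 2.95
#: contact interface half-width, as a fraction of the smaller cell radius
ADHESION_INTERFACE_BREADTH = 0.16


class PlacementError(RuntimeError):
    """Requested cell counts cannot be placed under the overlap policy."""


@dataclass
class SynthConfig:
    """Scene statistics.  Defaults describe a 256x256 crop where RBCs are
    4-6 px in radius and macrophages 10-16 px (~2.5x, preserving the
    5-7 um vs 13-20 um size ratio; the px/um factor itself is free).
    """

    size: int = 256
    rbc_radius: tuple[float, float] = (4.0, 6.0)
    mac_radius: tuple[float, float] = (10.0, 16.0)
    #: class-1 count range, used in rbc and mixed scenes
    rbc_count: tuple[int, int] = (8, 16)
    #: class-2 count range in single-kind macrophage scenes
    mac_count: tuple[int, int] = (2, 5)
    #: class-2 count range in mixed scenes (~8:1 RBC:macrophage by count)
    mixed_mac_count: tuple[int, int] = (1, 2)
    #: probability that a macrophage placement is an adhesive pair
    adhesion_prob: float = 0.1
    #: relative jitter of the ellipse axes around the drawn radius
    eccentricity: float = 0.15
    background_mean: float = 185.0
    cell_means: dict[int, float] = field(default_factory=lambda: {1: 95.0, 2: 120.0})
    cell_jitter: float = 6.0
    noise_std: float = 8.0
    illumination_amplitude: float = 15.0
    #: per-kind probability of 1-2 debris fibers (cultured macrophage
    #: scenes are dirtier than fresh-blood RBC scenes)
    debris_prob: dict[str, float] = field(
        default_factory=lambda: {"rbc": 0.1, "macrophage": 0.5, "mixed": 0.3}
    )
    debris_length: tuple[float, float] = (80.0, 120.0)
    debris_width: float = 2.5
    overlap: str = "none"  # "none" | "allow"
    #: minimum background gap between non-adhesive cells; must stay well
    #: above ADHESION_GAP so only adhesive contacts get bridged by
    #: threshold-based labeling
    margin: float = 3.0
    max_tries: int = 200

    def __post_init__(self) -> None:
        for name in ("rbc_radius", "mac_radius"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive non-degenerate range")
        if not self.mac_radius[0] > self.rbc_radius[1]:
            raise ValueError("macrophage min radius must exceed RBC max radius")
        if not 0.0 <= self.adhesion_prob <= 1.0:
            raise ValueError("adhesion_prob must be in [0, 1]")
        if self.overlap not in ("none", "allow"):
            raise ValueError("overlap policy must be 'none' or 'allow'")

    @classmethod
    def small(cls, **overrides) -> "SynthConfig":
        """64x64 preset used for desk-scale training experiments."""
        kw = dict(
            size=64,
            rbc_radius=(3.0, 5.0),
            mac_radius=(6.5, 10.0),
            rbc_count=(4, 8),
            mac_count=(1, 2),
            mixed_mac_count=(1, 2),
            debris_length=(20.0, 36.0),
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class Instance:
    """One generated cell: class value, center (row, col), ellipse axes
    (row, col semi-axes in px), rotation angle in radians, and whether it
    is part of an adhesive pair."""

    cls: int
    center: tuple[float, float]
    axes: tuple[float, float]
    angle: float
    adhesive: bool = False

    @property
    def radius(self) -> float:
        return max(self.axes)


@dataclass
class SynthScene:
    image: np.ndarray
    mask: np.ndarray
    true_counts: dict[int, int]
    instances: list[Instance]
    kind: str = "mixed"


def _sample_ellipse(cls: int, radius_range, cfg: SynthConfig, rng, adhesive=False,
                    center=None) -> Instance:
    r = rng.uniform(*radius_range)
    if adhesive:
        axes = (r, r)  # adhesive pairs are circles: contact geometry is controlled
        angle = 0.0
    else:
        e = cfg.eccentricity
        axes = (r * (1 + rng.uniform(-e, e)), r * (1 + rng.uniform(-e, e)))
        angle = rng.uniform(0, np.pi)
    return Instance(cls=cls, center=center or (0.0, 0.0), axes=axes, angle=angle,
                    adhesive=adhesive)


def _fits(inst: Instance, placed: list[Instance], cfg: SynthConfig, partner=None) -> bool:
    n = cfg.size
    r = inst.radius
    cr, cc = inst.center
    if not (r + 1 <= cr <= n - r - 2 and r + 1 <= cc <= n - r - 2):
        return False
    if cfg.overlap == "allow":
        return True
    for other in placed:
        if other is partner:
            continue
        d = np.hypot(cr - other.center[0], cc - other.center[1])
        if d <= r + other.radius + cfg.margin:
            return False
    return True


def _place_cells(kind: str, n1: int, n2: int, cfg: SynthConfig, rng) -> list[Instance]:
    placed: list[Instance] = []

    def place_one(cls, radius_range, adhesive=False):
        for _ in range(cfg.max_tries):
            inst = _sample_ellipse(cls, radius_range, cfg, rng, adhesive=adhesive)
            r = inst.radius
            inst.center = (rng.uniform(r + 1, cfg.size - r - 2),
                           rng.uniform(r + 1, cfg.size - r - 2))
            if _fits(inst, placed, cfg):
                placed.append(inst)
                return inst
        raise PlacementError(
            f"could not place a class-{cls} cell after {cfg.max_tries} tries"
        )

    def place_pair(radius_range):
        for _ in range(cfg.max_tries):
            r1 = rng.uniform(*radius_range)
            r2 = rng.uniform(*radius_range)
            d = ADHESION_DISTANCE_FACTOR * (r1 + r2)
            # flatten both cells so their bodies stay ADHESION_GAP apart
            shrink = (d - ADHESION_GAP) / (r1 + r2)
            a = Instance(cls=2, center=(0.0, 0.0), axes=(r1 * shrink, r1 * shrink),
                         angle=0.0, adhesive=True)
            b = Instance(cls=2, center=(0.0, 0.0), axes=(r2 * shrink, r2 * shrink),
                         angle=0.0, adhesive=True)
            ra, rb = a.radius, b.radius
            phi = rng.uniform(0, 2 * np.pi)
            ca = (rng.uniform(ra + 1, cfg.size - ra - 2),
                  rng.uniform(ra + 1, cfg.size - ra - 2))
            cb = (ca[0] + d * np.sin(phi), ca[1] + d * np.cos(phi))
            a.center, b.center = ca, cb
            if _fits(a, placed, cfg, partner=b) and _fits(b, placed + [a], cfg, partner=a):
                placed.extend([a, b])
                return
        raise PlacementError(
            f"could not place an adhesive pair after {cfg.max_tries} tries"
        )

    # macrophages first (larger, harder to place)
    remaining = n2
    while remaining > 0:
        if remaining >= 2 and rng.random() < cfg.adhesion_prob:
            place_pair(cfg.mac_radius)
            remaining -= 2
        else:
            place_one(2, cfg.mac_radius)
            remaining -= 1
    for _ in range(n1):
        place_one(1, cfg.rbc_radius)
    return placed


def _rasterize_mask(instances: list[Instance], size: int) -> np.ndarray:
    mask = np.zeros((size, size), dtype=np.uint8)
    for inst in instances:
        rr, cc = _draw_ellipse(inst.center[0], inst.center[1], inst.axes[0],
                               inst.axes[1], shape=(size, size), rotation=inst.angle)
        mask[rr, cc] = inst.cls
    return mask


def _adhesive_pairs(instances: list[Instance]) -> list[tuple[int, int]]:
    """Indices of adhesive partners; pairs are placed consecutively."""
    idx = [i for i, inst in enumerate(instances) if inst.adhesive]
    return [(idx[k], idx[k + 1]) for k in range(0, len(idx) - 1, 2)]


def _interface_polygon(a: Instance, b: Instance, size: int):
    """Pixels of the flattened contact zone between two adhering cells."""
    ca = np.asarray(a.center)
    cb = np.asarray(b.center)
    d = np.linalg.norm(cb - ca)
    u = (cb - ca) / d
    p = np.array([-u[1], u[0]])
    mid = ca + u * (a.radius + ADHESION_GAP / 2.0)
    t = ADHESION_GAP / 2.0 + ADHESION_INTERFACE_THICKNESS
    w = max(1.0, ADHESION_INTERFACE_BREADTH * min(a.radius, b.radius))
    corners = [mid + t * u + w * p, mid + t * u - w * p,
               mid - t * u - w * p, mid - t * u + w * p]
    rr = [c[0] for c in corners]
    cc = [c[1] for c in corners]
    return _draw_polygon(rr, cc, shape=(size, size))


def _debris_fiber(cfg: SynthConfig, cell_mask: np.ndarray, rng):
    """A thin rectangle (width ~2-3 px) avoiding all cells; None if
    no placement is found."""
    n = cfg.size
    for _ in range(cfg.max_tries):
        length = rng.uniform(*cfg.debris_length)
        theta = rng.uniform(0, np.pi)
        r0 = rng.uniform(2, n - 3)
        c0 = rng.uniform(2, n - 3)
        dr, dc = np.sin(theta), np.cos(theta)
        half_w = cfg.debris_width / 2.0
        pr, pc = -dc * half_w, dr * half_w  # perpendicular offset
        corners_r = [r0 + pr, r0 - pr, r0 + dr * length - pr, r0 + dr * length + pr]
        corners_c = [c0 + pc, c0 - pc, c0 + dc * length - pc, c0 + dc * length + pc]
        rr, cc = _draw_polygon(corners_r, corners_c, shape=(n, n))
        if rr.size < 4:
            continue
        if not cell_mask[rr, cc].any():
            return rr, cc
    return None


def generate_scene(cfg: SynthConfig, kind: str, rng: np.random.Generator) -> SynthScene:
    """Generate one synthetic scene of the given kind.

    ``rbc`` scenes contain only class-1 cells, ``macrophage`` scenes only
    class-2 cells (with adhesive pairs at the configured probability),
    ``mixed`` scenes both classes.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    if kind == "rbc":
        n1 = int(rng.integers(cfg.rbc_count[0], cfg.rbc_count[1] + 1))
        n2 = 0
    elif kind == "macrophage":
        n1 = 0
        n2 = int(rng.integers(cfg.mac_count[0], cfg.mac_count[1] + 1))
    else:
        n1 = int(rng.integers(cfg.rbc_count[0], cfg.rbc_count[1] + 1))
        n2 = int(rng.integers(cfg.mixed_mac_count[0], cfg.mixed_mac_count[1] + 1))

    instances = _place_cells(kind, n1, n2, cfg, rng)
    mask = _rasterize_mask(instances, cfg.size)

    n = cfg.size
    img = np.full((n, n), cfg.background_mean, dtype=np.float64)
    # smooth linear illumination gradient with a random direction
    if cfg.illumination_amplitude > 0:
        phi = rng.uniform(0, 2 * np.pi)
        rows = np.arange(n)[:, None] / max(n - 1, 1) - 0.5
        cols = np.arange(n)[None, :] / max(n - 1, 1) - 0.5
        img += 2 * cfg.illumination_amplitude * (np.sin(phi) * rows + np.cos(phi) * cols)
    # paint cells with per-cell intensity jitter
    intensities = []
    for inst in instances:
        level = cfg.cell_means[inst.cls] + rng.uniform(-cfg.cell_jitter,
                                                       cfg.cell_jitter)
        intensities.append(level)
        rr, cc = _draw_ellipse(inst.center[0], inst.center[1], inst.axes[0],
                               inst.axes[1], shape=(n, n), rotation=inst.angle)
        img[rr, cc] = level
    # adhesive pairs share a thin contact interface of cell material
    for ia, ib in _adhesive_pairs(instances):
        a, b = instances[ia], instances[ib]
        rr, cc = _interface_polygon(a, b, n)
        mask[rr, cc] = 2
        img[rr, cc] = 0.5 * (intensities[ia] + intensities[ib])
    # impurity fibers: on the image only, class 0 in the truth mask
    if rng.random() < cfg.debris_prob.get(kind, 0.0):
        for _ in range(int(rng.integers(1, 3))):
            fib = _debris_fiber(cfg, mask > 0, rng)
            if fib is not None:
                mean_cell = float(np.mean(list(cfg.cell_means.values())))
                img[fib] = mean_cell + rng.uniform(-cfg.cell_jitter, cfg.cell_jitter)
    if cfg.noise_std > 0:
        img += rng.normal(0.0, cfg.noise_std, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    counts = {1: sum(1 for i in instances if i.cls == 1),
              2: sum(1 for i in instances if i.cls == 2)}
    return SynthScene(image=img, mask=mask, true_counts=counts,
                      instances=instances, kind=kind)


def generate_dataset(cfg: SynthConfig, n_per_kind: dict[str, int] | int,
                     out_root: str | Path, seed: int) -> dict:
    """Write images, masks and a JSON manifest; reproducible from (cfg, seed).

    Layout: ``<out_root>/<kind>/{images,masks}/NNNN.png`` plus a
    ``manifest.json`` listing per-image true counts.
    """
    out_root = Path(out_root)
    if isinstance(n_per_kind, int):
        n_per_kind = {k: n_per_kind for k in KINDS}
    manifest: dict = {"seed": seed, "config": _config_dict(cfg), "scenes": []}
    for kind in KINDS:
        n = int(n_per_kind.get(kind, 0))
        if n == 0:
            continue
        img_dir = out_root / kind / "images"
        mask_dir = out_root / kind / "masks"
        img_dir.mkdir(parents=True, exist_ok=True)
        mask_dir.mkdir(parents=True, exist_ok=True)
        for i in range(n):
            scene = generate_scene_retry(
                cfg, kind, np.random.SeedSequence([seed, KINDS.index(kind), i])
            )
            ip = write_image(scene.image, img_dir / f"{i:04d}.png")
            mp = write_mask(scene.mask, mask_dir / f"{i:04d}.png")
            manifest["scenes"].append({
                "kind": kind,
                "image": str(ip.relative_to(out_root)),
                "mask": str(mp.relative_to(out_root)),
                "counts": {str(k): v for k, v in scene.true_counts.items()},
            })
    save_json(manifest, out_root / "manifest.json")
    return manifest


def scene_rng(seed: int, kind: str, index: int, attempt: int = 0) -> np.random.Generator:
    """Independent, reproducible stream for scene ``index`` of ``kind``."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, KINDS.index(kind), index, attempt])
    )


def generate_scene_retry(cfg: SynthConfig, kind: str, seed_seq: np.random.SeedSequence,
                         attempts: int = 8) -> SynthScene:
    """Rejection-sample scenes: a draw whose requested counts cannot be
    placed under the overlap policy is discarded and redrawn from a
    child stream (deterministic given ``seed_seq``)."""
    seq = seed_seq
    for _ in range(attempts):
        try:
            return generate_scene(cfg, kind, np.random.default_rng(seq))
        except PlacementError:
            seq = seq.spawn(1)[0]
    raise PlacementError(
        f"no placeable {kind} scene in {attempts} attempts; the configured "
        f"counts likely exceed what the canvas can hold"
    )


def split_from_manifest(manifest: dict, out_root: str | Path, kind: str,
                        role: str = "train") -> DatasetSplit:
    out_root = Path(out_root)
    scenes = [s for s in manifest["scenes"] if s["kind"] == kind]
    return DatasetSplit(images=[out_root / s["image"] for s in scenes],
                        masks=[out_root / s["mask"] for s in scenes], role=role)


def _config_dict(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    d["cell_means"] = {str(k): v for k, v in d["cell_means"].items()}
    return d
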