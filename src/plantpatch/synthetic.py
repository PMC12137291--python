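"""Procedural side-view plant images with pixel-level ground truth.

Emulates the imaging conditions of a high-throughput phenotyping booth:
one plant per image, photographed side-on against a near-black background
at a fixed scale.  A seeded recursive branching skeleton is rendered with
leaves at the nodes and — depending on the growth day relative to a
developmental schedule (buds, then flowers, then pods) — organs at the
branch tips.  Image and label mask are painted with the same strokes, so
the mask is exact by construction, and patch-level ground truth follows
the predominant-organ rule: a grid cell is labelled with the plant class
occupying the most pixels in it, or background when fewer than
``min_plant_pixels`` plant pixels are present (small slivers of organ at a
patch edge stay background, as a human annotator would leave them).

The growth model is phenomenological, not biomechanical: skeleton extent
scales linearly with day up to maturity, and each tip advances through
bud → flower → pod with a per-tip lag so organ classes overlap in time.
Class colors are chosen pairwise separable so that a trivial
nearest-palette-color classifier can recover the labels — a useful oracle
for testing everything downstream of the generator without any learning.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse, polygon

from .labels import CLASSES, CODE, PLANT_CLASSES
from .patch_grid import DEFAULT_PATCH_SIZE, ImageRecord

__all__ = [
    "PlantSpec",
    "GroundTruth",
    "generate_plant",
    "generate_series",
    "patch_labels_from_mask",
    "nearest_palette_mask",
    "oracle_patch_labels",
    "DEFAULT_PALETTE",
]

#: class -> (base RGB, per-channel uniform jitter). Bases are pairwise
#: separated by more than the sum of the two jitter radii in RGB space.
DEFAULT_PALETTE: dict[str, tuple[tuple[int, int, int], int]] = {
    "background": ((6, 6, 6), 6),
    "branch": ((110, 75, 35), 15),
    "leaf": ((30, 95, 30), 15),
    "bud": ((135, 210, 80), 12),
    "flower": ((235, 205, 45), 12),
    "pod": ((160, 190, 120), 10),
}


@dataclasses.dataclass
class PlantSpec:
    """Parameters of one synthetic plant at one growth day.

    The organ schedule must satisfy ``bud_day < flower_day < pod_day``
    (buds precede flowers precede pods).  ``seed`` fixes the plant's
    topology, so the same seed at increasing ``growth_day`` renders the
    same individual growing.
    """

    seed: int = 0
    canvas: tuple[int, int] = (600, 700)  # (width, height) px
    growth_day: int = 15
    depth: int = 3  # branching levels below the trunk
    children: tuple[int, int] = (2, 3)  # children per node (inclusive range)
    segment_length: float = 140.0  # trunk segment at full maturity, px
    angle_jitter: float = 22.0  # degrees
    mature_day: int = 15  # day the skeleton reaches full extent
    bud_day: int = 5
    flower_day: int = 8
    pod_day: int = 12
    organ_lag_days: int = 6  # per-tip developmental spread
    branch_width: float = 3.0
    leaf_radii: tuple[float, float] = (6.0, 11.0)  # semi-axes at maturity
    bud_radius: float = 3.0
    flower_radius: float = 7.0
    pod_size: tuple[float, float] = (8.0, 2.0)  # half-length, half-width
    palette: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )
    background_noise: int = 12

    def __post_init__(self) -> None:
        w, h = self.canvas
        if w < 100 or h < 100:
            raise ValueError(f"canvas must be at least 100x100, got {self.canvas}")
        if not (self.bud_day < self.flower_day < self.pod_day):
            raise ValueError(
                "organ schedule must satisfy bud_day < flower_day < pod_day, got "
                f"{self.bud_day} / {self.flower_day} / {self.pod_day}"
            )


@dataclasses.dataclass
class GroundTruth:
    """Pixel label mask plus the derived patch-level annotation table."""

    label_mask: np.ndarray  # H x W uint8, codes 0-5
    patch_labels: pd.DataFrame  # image_id, row, col, label, annotator_source


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class _Segment:
    x0: float  # unit-scale coordinates relative to the base point
    y0: float
    x1: float
    y1: float
    level: int


def _build_topology(spec: PlantSpec, rng: np.random.Generator):
    """Skeleton at unit scale: segments, leaf anchors, tips with lags."""
    segments: list[_Segment] = []
    leaves: list[tuple[float, float, float]] = []  # (x, y, orientation rad)
    tips: list[tuple[float, float]] = []

    def grow(x: float, y: float, angle: float, level: int) -> None:
        length = spec.segment_length * (0.78**level)
        x1 = x + length * math.cos(angle)
        y1 = y + length * math.sin(angle)
        segments.append(_Segment(x, y, x1, y1, level))
        # leaves beside the segment midpoint and at its end
        for frac in (0.5, 1.0):
            lx = x + frac * (x1 - x)
            ly = y + frac * (y1 - y)
            side = 1.0 if rng.random() < 0.5 else -1.0
            orient = angle + side * math.radians(55 + 25 * rng.random())
            leaves.append((lx, ly, orient))
        if level >= spec.depth:
            tips.append((x1, y1))
            return
        k = int(rng.integers(spec.children[0], spec.children[1] + 1))
        spread = math.radians(38.0)
        for j in range(k):
            offset = 0.0 if k == 1 else -spread + 2 * spread * j / (k - 1)
            jitter = math.radians(spec.angle_jitter) * (2 * rng.random() - 1)
            grow(x1, y1, angle + offset + jitter, level + 1)

    grow(0.0, 0.0, -math.pi / 2, 0)  # trunk points up (image y grows down)
    lags = [i % spec.organ_lag_days for i in range(len(tips))]
    return segments, leaves, tips, lags


# ---------------------------------------------------------------------------
# painting primitives (image and mask painted by the same stroke)
# ---------------------------------------------------------------------------


def _paint(img, mask, rr, cc, cls: str, palette, rng) -> None:
    if len(rr) == 0:
        return
    base, jitter = palette[cls]
    colors = np.clip(
        np.asarray(base)
        + rng.integers(-jitter, jitter + 1, size=(len(rr), 3)),
        0,
        255,
    )
    img[rr, cc] = colors
    mask[rr, cc] = CODE[cls]


def _thick_line(x0, y0, x1, y1, width, shape):
    """Pixel coords of a width-px quadrilateral along the segment."""
    dx, dy = x1 - x0, y1 - y0
    norm = math.hypot(dx, dy) or 1.0
    ox, oy = -dy / norm * width / 2, dx / norm * width / 2
    rr, cc = polygon(
        [y0 - oy, y0 + oy, y1 + oy, y1 - oy],
        [x0 - ox, x0 + ox, x1 + ox, x1 - ox],
        shape=shape,
    )
    return rr, cc


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_plant(
    spec: PlantSpec,
    image_id: str = "synthetic",
    plant_id: str = "plant00",
    capture_date: datetime.date | None = None,
    view: str = "side_0",
    patch_size: int = DEFAULT_PATCH_SIZE,
    min_plant_pixels: int = 5,
) -> tuple[ImageRecord, GroundTruth]:
    """Render one plant image and its exact ground truth.

    Deterministic for a fixed spec: topology is drawn from ``spec.seed``
    alone, pixel noise from ``(spec.seed, spec.growth_day)``.
    """
    w, h = spec.canvas
    shape = (h, w)
    topo_rng = np.random.default_rng(spec.seed)
    noise_rng = np.random.default_rng([spec.seed, spec.growth_day])
    segments, leaves, tips, lags = _build_topology(spec, topo_rng)

    scale = min(1.0, max(0.15, spec.growth_day / spec.mature_day))
    base_x, base_y = w / 2.0, h - 8.0

    img = noise_rng.integers(
        0, spec.background_noise + 1, size=(h, w, 3)
    ).astype(np.uint8)
    mask = np.zeros(shape, dtype=np.uint8)

    def at(x: float, y: float) -> tuple[float, float]:
        return base_x + x * scale, base_y + y * scale

    for seg in segments:
        (x0, y0), (x1, y1) = at(seg.x0, seg.y0), at(seg.x1, seg.y1)
        rr, cc = _thick_line(x0, y0, x1, y1, spec.branch_width, shape)
        _paint(img, mask, rr, cc, "branch", spec.palette, noise_rng)

    leaf_scale = 0.5 + 0.5 * scale
    a, b = spec.leaf_radii
    for lx, ly, orient in leaves:
        cx, cy = at(lx, ly)
        # offset the blade sideways so it sits beside the branch
        cx += math.cos(orient) * b * leaf_scale
        cy += math.sin(orient) * b * leaf_scale
        rr, cc = ellipse(
            cy, cx, a * leaf_scale, b * leaf_scale, shape=shape, rotation=orient
        )
        _paint(img, mask, rr, cc, "leaf", spec.palette, noise_rng)

    day = spec.growth_day
    for (tx, ty), lag in zip(tips, lags):
        cx, cy = at(tx, ty)
        if day >= spec.pod_day + lag:
            half_len, half_w = spec.pod_size
            angle = -math.pi / 2 + math.radians(25) * (1 if lag % 2 else -1)
            rr, cc = _thick_line(
                cx - half_len * math.cos(angle),
                cy - half_len * math.sin(angle),
                cx + half_len * math.cos(angle),
                cy + half_len * math.sin(angle),
                2 * half_w,
                shape,
            )
            _paint(img, mask, rr, cc, "pod", spec.palette, noise_rng)
        elif day >= spec.flower_day + lag:
            rr, cc = disk((cy, cx), spec.flower_radius, shape=shape)
            _paint(img, mask, rr, cc, "flower", spec.palette, noise_rng)
        elif day >= spec.bud_day + lag:
            rr, cc = disk((cy, cx), spec.bud_radius, shape=shape)
            _paint(img, mask, rr, cc, "bud", spec.palette, noise_rng)

    record = ImageRecord(
        image_id=image_id,
        plant_id=plant_id,
        capture_date=capture_date or datetime.date(2018, 6, 6),
        view=view,
        pixel_data=img,
    )
    truth = GroundTruth(
        label_mask=mask,
        patch_labels=patch_labels_from_mask(
            mask, patch_size, min_plant_pixels, image_id=image_id
        ),
    )
    return record, truth


def patch_labels_from_mask(
    mask: np.ndarray,
    patch_size: int = DEFAULT_PATCH_SIZE,
    min_plant_pixels: int = 5,
    image_id: str = "synthetic",
) -> pd.DataFrame:
    """Patch-level labels from a pixel mask via the predominant-organ rule.

    Per grid cell: background if fewer than *min_plant_pixels* plant
    pixels, else the plant class with the most pixels (ties to the earlier
    class in canonical order).  Covers every full cell of the grid.
    """
    h, w = mask.shape
    if h < patch_size or w < patch_size:
        raise ValueError(f"mask {w}x{h} smaller than one {patch_size}px patch")
    n_rows, n_cols = h // patch_size, w // patch_size
    cells = (
        mask[: n_rows * patch_size, : n_cols * patch_size]
        .reshape(n_rows, patch_size, n_cols, patch_size)
        .swapaxes(1, 2)
        .reshape(n_rows, n_cols, -1)
    )
    counts = np.stack(
        [(cells == CODE[c]).sum(axis=2) for c in PLANT_CLASSES], axis=2
    )
    plant_total = counts.sum(axis=2)
    best = counts.argmax(axis=2)  # first max -> canonical-order tie-break
    labels = np.where(
        plant_total < min_plant_pixels,
        0,
        best + 1,  # plant classes are codes 1..5
    )
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    return pd.DataFrame(
        {
            "image_id": image_id,
            "row": rows,
            "col": cols,
            "label": [CLASSES[k] for k in labels.ravel()],
            "annotator_source": "synthetic_ground_truth",
        }
    )


def generate_series(
    n_plants: int,
    n_days: int,
    base_spec: PlantSpec | None = None,
    seed: int = 0,
    start_date: datetime.date = datetime.date(2018, 6, 6),
) -> list[tuple[ImageRecord, GroundTruth]]:
    """A dated growth series: *n_plants* plants imaged on *n_days* days.

    Each plant keeps one topology across days while its skeleton extent
    grows and organs succeed bud → flower → pod.  Deterministic per
    (seed, plant index, day).
    """
    if n_plants < 1 or n_days < 1:
        raise ValueError("n_plants and n_days must be >= 1")
    base = base_spec or PlantSpec()
    out = []
    for i in range(n_plants):
        plant_seed = (seed + 7919 * (i + 1)) % (2**31)
        for d in range(n_days):
            spec = dataclasses.replace(base, seed=plant_seed, growth_day=d)
            image_id = f"plant{i:02d}_day{d:02d}_side0"
            record, truth = generate_plant(
                spec,
                image_id=image_id,
                plant_id=f"plant{i:02d}",
                capture_date=start_date + datetime.timedelta(days=d),
                view="side_0",
            )
            out.append((record, truth))
    return out


# ---------------------------------------------------------------------------
# palette oracle: a learning-free classifier over generated imagery
# ---------------------------------------------------------------------------


def nearest_palette_mask(
    pixels: np.ndarray, palette: dict | None = None
) -> np.ndarray:
    """Per-pixel nearest-palette-color label mask (codes 0-5).

    A trivial color-rule classifier: each pixel takes the class whose base
    palette color is nearest in RGB space.  On generated imagery with the
    default (separable) palette this inverts the renderer almost exactly.
    """
    palette = DEFAULT_PALETTE if palette is None else palette
    bases = np.asarray([palette[c][0] for c in CLASSES], dtype=np.float64)
    flat = pixels.reshape(-1, 3).astype(np.float64)
    d2 = ((flat[:, None, :] - bases[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1).astype(np.uint8).reshape(pixels.shape[:2])


def oracle_patch_labels(
    image: ImageRecord,
    palette: dict | None = None,
    patch_size: int = DEFAULT_PATCH_SIZE,
    min_plant_pixels: int = 5,
) -> pd.DataFrame:
    """Patch labels from the nearest-palette pixel classifier."""
    return patch_labels_from_mask(
        nearest_palette_mask(image.pixel_data, palette),
        patch_size,
        min_plant_pixels,
        image_id=image.image_id,
    )
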