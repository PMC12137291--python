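"""Deterministic grid slicing of whole-plant images and overlay reassembly.

An image of H×W pixels is tiled into non-overlapping ``patch_size`` ×
``patch_size`` squares from the top-left origin.  Only full patches are
kept: the right/bottom remainder strips (when ``patch_size`` does not
divide W or H) are excluded.  Patch identity is (image_id, row, col) with
0-based row-major ordering; pixel bounds are half-open intervals, so the
patch at (r, c) covers rows ``[r*p, (r+1)*p)`` and columns
``[c*p, (c+1)*p)``.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from pathlib import Path
import numpy as np
import pandas as pd
from PIL import Image

from .labels import check_label

logger = logging.getLogger(__name__)

VIEWS = ("side_0", "side_45", "side_90", "top")

DEFAULT_PATCH_SIZE = 10


@dataclasses.dataclass
class ImageRecord:
    """An RGB whole-plant image plus its capture metadata."""

    image_id: str
    plant_id: str
    capture_date: datetime.date
    view: str
    pixel_data: np.ndarray  # H x W x 3, uint8

    def __post_init__(self) -> None:
        self.pixel_data = np.asarray(self.pixel_data)
        if self.pixel_data.ndim != 3 or self.pixel_data.shape[2] != 3:
            raise ValueError(
                f"pixel_data must be HxWx3, got shape {self.pixel_data.shape}"
            )
        if self.pixel_data.dtype != np.uint8:
            if self.pixel_data.min() < 0 or self.pixel_data.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixel_data = self.pixel_data.astype(np.uint8)
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")

    @property
    def height(self) -> int:
        return self.pixel_data.shape[0]

    @property
    def width(self) -> int:
        return self.pixel_data.shape[1]


@dataclasses.dataclass(frozen=True)
class PatchGrid:
    """The tiling of one image: ``n_rows`` × ``n_cols`` full patches."""

    image_id: str
    patch_size: int
    n_rows: int
    n_cols: int

    @property
    def n_patches(self) -> int:
        return self.n_rows * self.n_cols

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


@dataclasses.dataclass(frozen=True)
class PatchRef:
    """Identity of one patch: image, grid position, and pixel bounds."""

    image_id: str
    row: int
    col: int
    patch_size: int = DEFAULT_PATCH_SIZE

    @property
    def pixel_bounds(self) -> tuple[int, int, int, int]:
        """(y0, x0, y1, x1) with half-open intervals [y0, y1) × [x0, x1)."""
        p = self.patch_size
        return (self.row * p, self.col * p, (self.row + 1) * p, (self.col + 1) * p)


def slice_image(
    image: ImageRecord, patch_size: int = DEFAULT_PATCH_SIZE
) -> tuple[PatchGrid, list[tuple[PatchRef, np.ndarray]]]:
    """Tile *image* into full ``patch_size`` squares in row-major order.

    Returns the grid plus a list of ``(PatchRef, block)`` pairs where each
    block is a ``patch_size × patch_size × 3`` view into the source array.
    Remainder strips that do not fill a whole patch are dropped (and their
    exclusion logged).

    Raises
    ------
    ValueError
        If either image dimension is smaller than one patch.
    """
    if patch_size < 1:
        raise ValueError(f"patch_size must be >= 1, got {patch_size}")
    h, w = image.height, image.width
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"image too small: {w}x{h} pixels cannot hold one "
            f"{patch_size}x{patch_size} patch"
        )
    n_rows, n_cols = h // patch_size, w // patch_size
    if h % patch_size or w % patch_size:
        logger.info(
            "excluding remainder strips: %d px bottom, %d px right of image %s",
            h % patch_size,
            w % patch_size,
            image.image_id,
        )
    grid = PatchGrid(image.image_id, patch_size, n_rows, n_cols)
    blocks = (
        image.pixel_data[: n_rows * patch_size, : n_cols * patch_size]
        .reshape(n_rows, patch_size, n_cols, patch_size, 3)
        .swapaxes(1, 2)
    )
    patches = [
        (PatchRef(image.image_id, r, c, patch_size), blocks[r, c])
        for r in range(n_rows)
        for c in range(n_cols)
    ]
    return grid, patches


def patch_manifest(grid: PatchGrid) -> pd.DataFrame:
    """Patch coordinate table: image_id, row, col, x0, y0, x1, y1."""
    rows, cols = np.divmod(np.arange(grid.n_patches), grid.n_cols)
    p = grid.patch_size
    return pd.DataFrame(
        {
            "image_id": grid.image_id,
            "row": rows,
            "col": cols,
            "x0": cols * p,
            "y0": rows * p,
            "x1": (cols + 1) * p,
            "y1": (rows + 1) * p,
        }
    )


#: Default per-class overlay colors (RGB).
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    "background": (80, 80, 80),
    "branch": (214, 39, 40),
    "leaf": (44, 160, 44),
    "bud": (31, 119, 180),
    "flower": (255, 215, 0),
    "pod": (148, 103, 189),
}


def reassemble_overlay(
    grid: PatchGrid,
    predictions: pd.DataFrame,
    image: ImageRecord,
    palette: dict[str, tuple[int, int, int]] | None = None,
    alpha: float = 0.5,
    tint_background: bool = True,
) -> np.ndarray:
    """Tint each predicted patch's region with its class color at opacity *alpha*.

    *predictions* needs columns ``row``, ``col``, ``final_label`` (a subset of
    grid cells).  Unpredicted cells and remainder strips keep the original
    pixels.  With ``tint_background=False``, background-class cells are left
    untinted as well.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    palette = dict(DEFAULT_PALETTE if palette is None else palette)
    out = image.pixel_data.astype(np.float64).copy()
    p = grid.patch_size
    for row, col, label in predictions[["row", "col", "final_label"]].itertuples(
        index=False
    ):
        check_label(label)
        if not grid.contains(row, col):
            raise ValueError(
                f"patch out of bounds: ({row}, {col}) not in "
                f"{grid.n_rows}x{grid.n_cols} grid"
            )
        if label == "background" and not tint_background:
            continue
        color = np.asarray(palette[label], dtype=np.float64)
        region = out[row * p : (row + 1) * p, col * p : (col + 1) * p]
        region *= 1.0 - alpha
        region += alpha * color
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def read_image(
    path: str | Path,
    image_id: str | None = None,
    plant_id: str = "unknown",
    capture_date: datetime.date | None = None,
    view: str = "side_0",
) -> ImageRecord:
    """Load an 8-bit RGB PNG or TIFF into an :class:`ImageRecord`."""
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("RGB"))
    return ImageRecord(
        image_id=image_id or path.stem,
        plant_id=plant_id,
        capture_date=capture_date or datetime.date.today(),
        view=view,
        pixel_data=arr,
    )


def write_image(arr: np.ndarray, path: str | Path) -> None:
    """Save an HxWx3 uint8 array as PNG/TIFF (by extension)."""
    Image.fromarray(np.asarray(arr, dtype=np.uint8)).save(path)
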