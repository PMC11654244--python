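"""Single-cell grid montages: crop, tile, contrast-adjust, 8-bit downscale.

Segmented cells are cropped as fixed 65x65-pixel boxes centered on their
centroids and tiled row-major into a 20x20 grid, giving one 1,300x1,300
montage per strain and channel.  Tiling preserves raw intensities so that
expression noise across cells stays comparable; only the final display step
linearly rescales the contrast so that 0.35% of pixels saturate.  Brightfield
montages are scaled down to 8 bits, where intensity variations carry no
information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellCrop",
    "MontageImage",
    "crop_cells",
    "assemble_grid",
    "adjust_contrast",
    "to_8bit",
]

BOX_SIZE = 65
GRID_DIMS = (20, 20)
SATURATE_FRACTION = 0.0035


@dataclass
class CellCrop:
    """A fixed-size box around one cell, raw intensities, zero-padded edges."""

    strain_id: str
    cell_id: str
    channel: str
    pixels: np.ndarray
    source_position: tuple[int, int]  # (row, col) of the centroid in the frame


@dataclass
class MontageImage:
    strain_id: str
    channel: str
    grid_dims: tuple[int, int]
    box_size: int
    pixels: np.ndarray
    n_cells_placed: int
    contrast: dict | None = None  # set by adjust_contrast

    def tile(self, row: int, col: int) -> np.ndarray:
        """Extract one grid tile (0-based)."""
        b = self.box_size
        return self.pixels[row * b : (row + 1) * b, col * b : (col + 1) * b]


def crop_cells(
    image: np.ndarray,
    centroids: pd.DataFrame,
    box_size: int = BOX_SIZE,
    strain_id: str = "",
    channel: str = "GFP",
) -> list[CellCrop]:
    """Crop a square box around each centroid, zero-padding at frame edges.

    ``centroids`` needs columns x, y (pixel coordinates, origin top-left) and
    optionally cell_id.  Non-integer centroids are floored.  For an odd box
    the crop's center pixel is the centroid pixel.  Centroids outside the
    frame are skipped with a warning.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    h, w = img.shape
    half = box_size // 2
    crops: list[CellCrop] = []
    ids = centroids["cell_id"] if "cell_id" in centroids else centroids.index.astype(str)
    for cid, x, y in zip(ids, centroids["x"], centroids["y"]):
        cy, cx = int(np.floor(y)), int(np.floor(x))
        if not (0 <= cy < h and 0 <= cx < w):
            warnings.warn(f"centroid {cid} at ({x}, {y}) outside frame; skipped", stacklevel=2)
            continue
        box = np.zeros((box_size, box_size), dtype=img.dtype)
        r0, r1 = cy - half, cy + half + 1
        c0, c1 = cx - half, cx + half + 1
        sr0, sc0 = max(r0, 0), max(c0, 0)
        sr1, sc1 = min(r1, h), min(c1, w)
        box[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = img[sr0:sr1, sc0:sc1]
        crops.append(CellCrop(strain_id, str(cid), channel, box, (cy, cx)))
    return crops


def assemble_grid(
    crops: Sequence[CellCrop],
    grid_dims: tuple[int, int] = GRID_DIMS,
    strain_id: str | None = None,
    channel: str | None = None,
) -> MontageImage:
    """Tile crops row-major onto a fixed canvas; unfilled tiles stay zero.

    20x20 tiles of 65x65 crops give the canonical 1,300x1,300 montage.  Up
    to rows*cols crops are placed; any excess is truncated with a warning.
    Intensities are copied verbatim.
    """
    rows, cols = grid_dims
    capacity = rows * cols
    crops = list(crops)
    if len(crops) > capacity:
        warnings.warn(
            f"{len(crops)} crops exceed grid capacity {capacity}; truncating", stacklevel=2
        )
        crops = crops[:capacity]
    if crops:
        box = crops[0].pixels.shape[0]
        for c in crops:
            if c.pixels.shape != (box, box):
                raise ValueError("all crops must share the same box size")
        dtype = crops[0].pixels.dtype
        sid = strain_id if strain_id is not None else crops[0].strain_id
        chan = channel if channel is not None else crops[0].channel
    else:
        box, dtype, sid, chan = BOX_SIZE, np.uint16, strain_id or "", channel or ""
    canvas = np.zeros((rows * box, cols * box), dtype=dtype)
    for i, crop in enumerate(crops):
        r, c = divmod(i, cols)
        canvas[r * box : (r + 1) * box, c * box : (c + 1) * box] = crop.pixels
    return MontageImage(sid, chan, grid_dims, box, canvas, len(crops))


def _dtype_levels(arr: np.ndarray) -> tuple[float, int]:
    """(display maximum, number of representable levels) for an image array."""
    if np.issubdtype(arr.dtype, np.integer):
        top = float(np.iinfo(arr.dtype).max)
        return top, int(top) + 1
    return 1.0, 2**16  # floats are rescaled to [0, 1]


def adjust_contrast(
    montage: MontageImage,
    saturate_fraction: float = SATURATE_FRACTION,
    mode: str = "top",
) -> MontageImage:
    """Linear contrast stretch saturating ~``saturate_fraction`` of pixels.

    ``mode="top"`` (default) anchors the lower bound at the image minimum
    and clips at the (1 - saturate_fraction) quantile so only bright pixels
    saturate — the right convention for fluorescence display.  ``"split"``
    spends half the budget on each end.  Constant images are returned
    unchanged (flagged in the contrast record).  Pure function: the input
    montage is untouched.
    """
    if not (0.0 < saturate_fraction < 1.0):
        raise ValueError("saturate_fraction must be in (0, 1)")
    px = montage.pixels
    vals = px.astype(float)
    if mode == "top":
        lo = float(vals.min())
        hi = float(np.quantile(vals, 1.0 - saturate_fraction))
    elif mode == "split":
        lo = float(np.quantile(vals, saturate_fraction / 2.0))
        hi = float(np.quantile(vals, 1.0 - saturate_fraction / 2.0))
    else:
        raise ValueError(f"unknown contrast mode {mode!r}")
    top, _levels = _dtype_levels(px)
    if hi <= lo:  # constant (or near-constant) image: nothing to stretch
        out = MontageImage(
            montage.strain_id, montage.channel, montage.grid_dims, montage.box_size,
            px.copy(), montage.n_cells_placed,
            contrast={"saturate_fraction": saturate_fraction, "mode": mode,
                      "clip_low": lo, "clip_high": hi, "constant": True},
        )
        return out
    scaled = (np.clip(vals, lo, hi) - lo) / (hi - lo) * top
    if np.issubdtype(px.dtype, np.integer):
        scaled = np.floor(scaled + 0.5).astype(px.dtype)
    return MontageImage(
        montage.strain_id, montage.channel, montage.grid_dims, montage.box_size,
        scaled, montage.n_cells_placed,
        contrast={"saturate_fraction": saturate_fraction, "mode": mode,
                  "clip_low": lo, "clip_high": hi, "constant": False},
    )


def to_8bit(montage: MontageImage) -> MontageImage:
    """Min-max rescale to 8 bits (rounding half-up), e.g. for brightfield."""
    px = montage.pixels.astype(float)
    lo, hi = float(px.min()), float(px.max())
    if hi > lo:
        scaled = (px - lo) / (hi - lo) * 255.0
    else:
        scaled = np.zeros_like(px)
    out = np.floor(scaled + 0.5).astype(np.uint8)
    return MontageImage(
        montage.strain_id, montage.channel, montage.grid_dims, montage.box_size,
        out, montage.n_cells_placed, contrast=montage.contrast,
    )
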