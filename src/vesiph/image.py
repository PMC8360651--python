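"""Single-channel image container and plain-TIFF I/O.

All modules share one coordinate convention: 0-based pixel indices,
row-major ``(row, col)``; physical position in microns is ``index *
um_per_px``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Image2D", "read_tiff_channels", "write_tiff_channels"]


@dataclass
class Image2D:
    """A single fluorescence channel with physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2D non-negative intensity grid (float internally; quantized to
        ``bit_depth`` only on write).
    channel_tag : str
        Channel label, conventionally ``"O"`` (pH-sensitive) or ``"R"``
        (pH-insensitive reference).
    um_per_px : float
        Microns per pixel, > 0.
    bit_depth : int
        Acquisition bit depth used when writing to disk.
    """

    pixels: np.ndarray
    channel_tag: str = "other"
    um_per_px: float = 0.1
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D requires a 2D pixel grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        return replace(self, pixels=pixels)


def _quantize(img: Image2D) -> np.ndarray:
    top = 2**img.bit_depth - 1
    return np.clip(np.rint(img.pixels), 0, top).astype(
        np.uint16 if img.bit_depth <= 16 else np.uint32
    )


def write_tiff_channels(path: str | Path, images: list[Image2D], multipage: bool = True) -> list[Path]:
    """Write channels as one multi-page TIFF or separate single-channel files.

    Returns the list of files written. Intensities are quantized to the
    image's bit depth.
    """
    path = Path(path)
    if multipage:
        tifffile.imwrite(path, np.stack([_quantize(im) for im in images]))
        return [path]
    written = []
    for im in images:
        p = path.with_name(f"{path.stem}_{im.channel_tag}{path.suffix}")
        tifffile.imwrite(p, _quantize(im))
        written.append(p)
    return written


def read_tiff_channels(
    path: str | Path, channel_tags: list[str] | None = None, um_per_px: float = 0.1
) -> list[Image2D]:
    """Read a single- or multi-page TIFF into a list of Image2D.

    ``channel_tags`` names the pages in order (defaults to O, R, then
    ``other``).
    """
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if channel_tags is None:
        channel_tags = (["O", "R"] + ["other"] * arr.shape[0])[: arr.shape[0]]
    return [
        Image2D(pixels=page.astype(float), channel_tag=tag, um_per_px=um_per_px)
        for page, tag in zip(arr, channel_tags)
    ]
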