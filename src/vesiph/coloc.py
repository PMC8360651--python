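"""Colocalization readouts: line-profile puncta matching and per-ROI
Pearson correlation.

Percent colocalization is deliberately asymmetric: the number of red
puncta that have a green partner within a matching tolerance, out of all
red puncta along the neurite. Matching is greedy one-to-one by
increasing pair distance, so no green punctum can claim two red puncta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, signal, stats

from .image import Image2D
from .rois import LineROI

__all__ = [
    "LineROI",
    "Profile",
    "PeakSet",
    "ColocResult",
    "extract_line_profile",
    "detect_puncta_1d",
    "percent_colocalization",
    "pearson_roi",
]

#: default matching tolerance, ~ punctum radius at 60x magnification
DEFAULT_TOLERANCE_UM = 0.5


@dataclass
class Profile:
    """Intensity along a line ROI: positions in um starting at 0, one
    intensity vector per channel."""

    positions_um: np.ndarray
    intensities: dict[str, np.ndarray]

    def __post_init__(self):
        for tag, v in self.intensities.items():
            if len(v) != len(self.positions_um):
                raise ValueError(f"channel {tag}: length mismatch with positions")
        if len(self.positions_um) and self.positions_um[0] != 0:
            raise ValueError("positions must start at 0")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class PeakSet:
    positions_um: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray

    def __len__(self):
        return len(self.positions_um)


@dataclass
class ColocResult:
    n_red_puncta: int
    n_matched: int
    percent_coloc: float
    match_tolerance_um: float
    pearson_r: float | None = None
    pairs: list[tuple[int, int]] | None = None  # (red index, green index)


def extract_line_profile(images: Sequence[Image2D], roi: LineROI) -> Profile:
    """Bilinear line profile at 1-px steps, averaged over ``width_px``
    perpendicular offsets, per channel."""
    if not images:
        raise ValueError("at least one channel required")
    um_per_px = images[0].um_per_px
    n = int(round(roi.length_px)) + 1
    t = np.linspace(0.0, roi.length_px, n)
    dr, dc = roi.direction
    nr, nc = roi.normal
    offsets = np.arange(roi.width_px) - roi.width_px // 2
    (r0, c0) = roi.start
    rows = r0 + t[None, :] * dr + offsets[:, None] * nr
    cols = c0 + t[None, :] * dc + offsets[:, None] * nc
    h, w = images[0].shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() > h - 1 or cols.max() > w - 1:
        raise ValueError("line ROI (including width) extends outside the image")
    intensities = {}
    for img in images:
        if img.shape != (h, w):
            raise ValueError("all channels must share one shape")
        vals = ndimage.map_coordinates(
            img.pixels, np.vstack([rows.ravel(), cols.ravel()]), order=1
        ).reshape(rows.shape)
        intensities[img.channel_tag] = vals.mean(axis=0)
    return Profile(positions_um=t * um_per_px, intensities=intensities)


def detect_puncta_1d(
    positions_um: np.ndarray,
    values: np.ndarray,
    min_prominence: float | None = None,
    min_sep_um: float = 0.5,
) -> PeakSet:
    """Local maxima of a profile with prominence and separation floors.

    ``min_prominence`` defaults to 20% of the profile's dynamic range
    (robust to baseline drift); prominence follows the usual convention
    of measuring against the lower flanking minimum. A flat profile
    yields an empty set.
    """
    values = np.asarray(values, dtype=float)
    positions_um = np.asarray(positions_um, dtype=float)
    if len(values) < 3:
        raise ValueError("profile too short for peak detection")
    rng = float(values.max() - values.min())
    if rng == 0:
        return PeakSet(np.array([]), np.array([]), np.array([]))
    if min_prominence is None:
        min_prominence = 0.2 * rng
    step = float(np.mean(np.diff(positions_um)))
    distance = max(1, int(math.ceil(min_sep_um / step)))
    idx, props = signal.find_peaks(values, prominence=min_prominence, distance=distance)
    return PeakSet(positions_um[idx], values[idx], props["prominences"])


def percent_colocalization(
    red: PeakSet | np.ndarray,
    green: PeakSet | np.ndarray,
    tolerance_um: float = DEFAULT_TOLERANCE_UM,
) -> ColocResult:
    """Fraction of red puncta with a green partner within tolerance.

    Candidate pairs within tolerance are sorted by distance and accepted
    greedily, each red and each green punctum at most once.
    """
    red_pos = np.asarray(red.positions_um if isinstance(red, PeakSet) else red, dtype=float)
    green_pos = np.asarray(
        green.positions_um if isinstance(green, PeakSet) else green, dtype=float
    )
    if red_pos.size == 0:
        raise ValueError("undefined denominator: no red puncta")
    pairs = [
        (abs(r - g), i, j)
        for i, r in enumerate(red_pos)
        for j, g in enumerate(green_pos)
        if abs(r - g) <= tolerance_um
    ]
    pairs.sort()
    used_r, used_g, matched = set(), set(), []
    for _, i, j in pairs:
        if i in used_r or j in used_g:
            continue
        used_r.add(i)
        used_g.add(j)
        matched.append((i, j))
    n_red = int(red_pos.size)
    return ColocResult(
        n_red_puncta=n_red,
        n_matched=len(matched),
        percent_coloc=100.0 * len(matched) / n_red,
        match_tolerance_um=tolerance_um,
        pairs=matched,
    )


def pearson_roi(image_a: Image2D, image_b: Image2D, mask: np.ndarray) -> float:
    """Pearson correlation of two channels over a pixel mask."""
    mask = np.asarray(mask, dtype=bool)
    if image_a.shape != image_b.shape or mask.shape != image_a.shape:
        raise ValueError("images and mask must share one shape")
    a = image_a.pixels[mask]
    b = image_b.pixels[mask]
    if a.size < 2:
        raise ValueError("mask must contain at least 2 pixels")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a channel over the mask")
    return float(stats.pearsonr(a, b).statistic)
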