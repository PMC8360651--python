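"""Line ROI geometry shared by the profile and pH modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LineROI"]


@dataclass(frozen=True)
class LineROI:
    """A straight line ROI in pixel coordinates with a perpendicular
    averaging width.

    ``start``/``end`` are (row, col); ``width_px`` is the odd number of
    1-px-spaced parallel samples averaged perpendicular to the line.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    width_px: int = 1

    def __post_init__(self):
        if tuple(self.start) == tuple(self.end):
            raise ValueError("line ROI endpoints must be distinct")
        if self.width_px < 1 or self.width_px % 2 == 0:
            raise ValueError("width_px must be odd and >= 1")

    @property
    def length_px(self) -> float:
        (r0, c0), (r1, c1) = self.start, self.end
        return float(np.hypot(r1 - r0, c1 - c0))

    def length_um(self, um_per_px: float) -> float:
        return self.length_px * um_per_px

    @property
    def direction(self) -> tuple[float, float]:
        (r0, c0), (r1, c1) = self.start, self.end
        L = self.length_px
        return ((r1 - r0) / L, (c1 - c0) / L)

    @property
    def normal(self) -> tuple[float, float]:
        dr, dc = self.direction
        return (-dc, dr)
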