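"""Ratiometric O/R-versus-pH calibration.

The pH-sensitive ("O") to pH-insensitive ("R") intensity ratio of the
sensor follows a Henderson-Hasselbalch sigmoid with a free Hill
coefficient,

    value(pH) = r_min + (r_max - r_min) / (1 + 10 ** (n * (pH - pKa))),

which decreases monotonically with pH (n > 0). This module fits that
curve to a measured calibration series, rescales in-specimen ratios onto
the calibration axis using an internal calibrator of known pH
(coelomocyte lysosomes, taken as pH 5.5), inverts ratios to pH
analytically, and derives the two-state surface-versus-internalized
mixture bound from an ensemble ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .image import Image2D
from .rois import LineROI

__all__ = [
    "CalibrationCurve",
    "PHMeasurement",
    "MixtureBound",
    "sigmoid_value",
    "fit_calibration",
    "normalize_to_internal_calibrator",
    "invert_calibration",
    "fold_change",
    "surface_fraction_bound",
    "neuron_line_roi",
    "INTERNAL_CALIBRATOR_PH",
]

logger = logging.getLogger(__name__)

#: pH assigned to the coelomocyte-lysosome internal calibrator.
INTERNAL_CALIBRATOR_PH = 5.5


def sigmoid_value(ph, r_min: float, r_max: float, pka: float, hill_n: float):
    """Evaluate the 4-parameter O/R sigmoid at ``ph`` (scalar or array)."""
    ph = np.asarray(ph, dtype=float)
    out = r_min + (r_max - r_min) / (1.0 + 10.0 ** (hill_n * (ph - pka)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted O/R-versus-pH sigmoid.

    ``value(pH)`` is strictly decreasing and bounded in
    ``(r_min, r_max)``; ``fit_residual`` is the RMS of the fit.
    """

    r_min: float
    r_max: float
    pka: float
    hill_n: float
    fit_residual: float = 0.0

    def __post_init__(self):
        if not self.r_min < self.r_max:
            raise ValueError("requires r_min < r_max")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be positive for a decreasing curve")

    def value(self, ph):
        return sigmoid_value(ph, self.r_min, self.r_max, self.pka, self.hill_n)

    def to_dict(self) -> dict:
        return {
            "r_min": self.r_min,
            "r_max": self.r_max,
            "pka": self.pka,
            "hill_n": self.hill_n,
            "fit_residual": self.fit_residual,
        }


@dataclass
class PHMeasurement:
    """Per-ROI ratiometric measurement and its pH estimate.

    ``o_over_r`` is the raw ratio of background-subtracted means;
    ``normalized_o_over_r`` exists only after internal-calibrator
    scaling; ``ph_flag`` is one of ``in_range``, ``at_plateau``,
    ``above_range``.
    """

    roi_id: int | str
    mean_o: float
    mean_r: float
    normalized_o_over_r: float | None = None
    ph_estimate: float | None = None
    ph_flag: str | None = None

    @property
    def o_over_r(self) -> float:
        if self.mean_r <= 0:
            raise ValueError(f"ROI {self.roi_id}: mean_r must be > 0 to form O/R")
        return self.mean_o / self.mean_r


@dataclass(frozen=True)
class MixtureBound:
    """Two-state bound on the surface fraction from an ensemble ratio."""

    r_surface: float
    r_internal: float
    epsilon: float
    f_surface_max: float
    f_internal_min: float


# ---------------------------------------------------------------------------
# fitting


def fit_calibration(
    series: pd.DataFrame,
    fit_config: dict | None = None,
) -> CalibrationCurve:
    """Least-squares fit of the O/R sigmoid to a calibration series.

    ``series`` needs columns ``ph`` and ``o_over_r`` (a ``rep`` column is
    tolerated and ignored: replicates are fit as individual points).
    The fit is multi-start over a fixed grid of pKa and Hill-coefficient
    seeds so the result is deterministic; bounds keep ``r_min >= 0`` and
    ``hill_n`` in [0.5, 4].

    Raises
    ------
    ValueError
        If fewer than 4 distinct pH points are supplied or the RMS
        residual exceeds ``fit_config["residual_ceiling"]``.
    """
    cfg = {"residual_ceiling": 0.2, "pka_grid": np.arange(5.5, 8.6, 0.5),
           "hill_grid": (0.5, 1.0, 2.0)}
    cfg.update(fit_config or {})
    ph = np.asarray(series["ph"], dtype=float)
    y = np.asarray(series["o_over_r"], dtype=float)
    if np.unique(ph).size < 4:
        raise ValueError("calibration fit needs >= 4 distinct pH points")
    if np.any(y <= 0):
        raise ValueError("o_over_r values must be positive")

    span0 = max(y.max() - y.min(), 1e-3)
    lo = np.array([0.0, 1e-6, 3.0, 0.5])
    hi = np.array([np.inf, np.inf, 10.0, 4.0])

    def resid(p):
        r_min, span, pka, n = p
        return sigmoid_value(ph, r_min, r_min + span, pka, n) - y

    best = None
    for pka0 in cfg["pka_grid"]:
        for n0 in cfg["hill_grid"]:
            p0 = np.clip([max(y.min(), 0.0), span0, pka0, n0], lo, hi)
            try:
                sol = optimize.least_squares(resid, p0, bounds=(lo, hi))
            except Exception:  # pragma: no cover - defensive
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise ValueError("calibration fit failed to converge from any start")
    r_min, span, pka, n = best.x
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    if rms > cfg["residual_ceiling"]:
        raise ValueError(
            f"calibration fit residual {rms:.4f} exceeds ceiling "
            f"{cfg['residual_ceiling']}"
        )
    return CalibrationCurve(float(r_min), float(r_min + span), float(pka), float(n), rms)


# ---------------------------------------------------------------------------
# internal calibrator and inversion


def normalize_to_internal_calibrator(
    measurements: Sequence[PHMeasurement],
    clm_measurements: Sequence[PHMeasurement],
    curve: CalibrationCurve,
) -> list[PHMeasurement]:
    """Rescale raw O/R values onto the calibration axis.

    The mean O/R of the coelomocyte (internal calibrator) ROIs is mapped
    to ``curve.value(5.5)``; the same multiplicative factor is applied to
    every measurement, so channel-wide gain factors cancel.
    """
    if len(clm_measurements) == 0:
        raise ValueError("at least one coelomocyte ROI is required")
    clm_mean = float(np.mean([m.o_over_r for m in clm_measurements]))
    if clm_mean <= 0:
        raise ValueError("coelomocyte mean O/R must be positive")
    scale = curve.value(INTERNAL_CALIBRATOR_PH) / clm_mean
    logger.info("internal calibrator: mean O/R %.4f -> scale %.4f", clm_mean, scale)
    out = []
    for m in measurements:
        out.append(replace(m, normalized_o_over_r=m.o_over_r * scale))
    return out


def invert_calibration(
    curve: CalibrationCurve,
    normalized_o_over_r: float,
    plateau_epsilon: float = 0.02,
) -> tuple[float, str]:
    """Analytic inversion of the fitted sigmoid.

    Ratios within ``plateau_epsilon`` of the acidic plateau ``r_max`` are
    flagged ``at_plateau`` and reported as pH <= 6 (point estimate
    clamped to 6.0): below ~pH 6 the sensor saturates and reports the
    same maximal ratio for any acidity, its "digital" regime. Ratios
    below ``curve.value(9)`` are flagged ``above_range``.
    """
    v = normalized_o_over_r
    if not math.isfinite(v):
        raise ValueError("normalized O/R must be finite")
    if v >= curve.r_max - plateau_epsilon:
        return 6.0, "at_plateau"
    if v <= curve.r_min:
        raise ValueError("ratio at or below r_min has no finite inverse")
    ph = curve.pka + math.log10((curve.r_max - v) / (v - curve.r_min)) / curve.hill_n
    flag = "above_range" if v < curve.value(9.0) else "in_range"
    return float(ph), flag


def fold_change(curve: CalibrationCurve, ph_a: float, ph_b: float) -> float:
    """O/R contrast value(ph_b)/value(ph_a) between two pH values."""
    return float(curve.value(ph_b) / curve.value(ph_a))


def surface_fraction_bound(
    r_surface: float, r_internal: float, epsilon: float
) -> MixtureBound:
    """Two-state bound on the surface-resident sensor fraction.

    Under the linear mixture model with equal per-device R emission, an
    ensemble of fraction f at the surface ratio and 1-f at the internal
    ratio reads f*r_surface + (1-f)*r_internal. The largest f whose
    ensemble ratio stays within ``epsilon`` of the pure internal value is

        f_surface_max = min(1, epsilon / (r_internal - r_surface)).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if not 0 <= r_surface < r_internal:
        raise ValueError("components unidentifiable: requires r_internal > r_surface >= 0")
    f_max = min(1.0, epsilon / (r_internal - r_surface))
    return MixtureBound(r_surface, r_internal, epsilon, f_max, 1.0 - f_max)


# ---------------------------------------------------------------------------
# line ROI placement


def neuron_line_roi(
    image: Image2D,
    anchor_point: tuple[float, float],
    length_um: float = 5.0,
    width_px: int = 1,
    n_angles: int = 180,
) -> LineROI:
    """Place a line ROI of fixed physical length along the local bright axis.

    The line is centered at ``anchor_point`` (row, col) and oriented
    along the direction that maximizes summed bilinear-sampled intensity
    over a discrete grid of ``n_angles`` angles in [0, pi) - i.e.
    parallel to the maximum-intensity region of the neurite.
    """
    r0, c0 = anchor_point
    h, w = image.shape
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("anchor outside image")
    half_px = 0.5 * length_um / image.um_per_px
    n_samples = int(round(length_um / image.um_per_px)) + 1
    t = np.linspace(-half_px, half_px, n_samples)
    best_theta, best_sum = None, -np.inf
    for theta in np.linspace(0.0, np.pi, n_angles, endpoint=False):
        rows = r0 + t * np.sin(theta)
        cols = c0 + t * np.cos(theta)
        vals = ndimage.map_coordinates(
            image.pixels, np.vstack([rows, cols]), order=1, mode="nearest"
        )
        s = float(vals.sum())
        if s > best_sum:
            best_sum, best_theta = s, theta
    if best_sum <= 0:
        raise ValueError("anchor sits in a zero-intensity region")
    dr, dc = math.sin(best_theta), math.cos(best_theta)
    return LineROI(
        start=(r0 - half_px * dr, c0 - half_px * dc),
        end=(r0 + half_px * dr, c0 + half_px * dc),
        width_px=width_px,
    )
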