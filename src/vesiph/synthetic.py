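"""Synthetic two-channel fluorescence scenes with known ground truth.

Every downstream stage (segmentation, ratiometry, colocalization) is
exercised on scenes generated here, so each scene carries a ground-truth
twin of what a real specimen would hide: per-object position, size, true
pH, and sensor copy number.

The photometric model is the standard CCD/EMCCD chain: each object
carries ``device_count`` sensor copies; the R (pH-insensitive) channel
collects ``device_count * gain_r`` photons per object and the O
(pH-sensitive) channel ``device_count * gain_o * value(pH)`` photons,
where ``value`` is the normalized O/R calibration sigmoid. Object
photons are spread uniformly over the object footprint, blurred by a
Gaussian PSF, offset by a constant background, then subjected to Poisson
shot noise and additive Gaussian read noise. Scenes are byte-for-byte
reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .calibration import CalibrationCurve, sigmoid_value
from .image import Image2D, write_tiff_channels

__all__ = [
    "TwoStateMix",
    "SceneParams",
    "ObjectTruth",
    "SceneGroundTruth",
    "CalibrationFixture",
    "ColocGroundTruth",
    "build_calibration_fixture",
    "generate_vesicle_scene",
    "generate_membrane_scene",
    "generate_calibration_series",
    "generate_coloc_scene",
    "write_scene",
]


# ---------------------------------------------------------------------------
# parameters and ground truth containers


@dataclass(frozen=True)
class TwoStateMix:
    """Two-population pH specification: a fraction ``f_surface`` of the
    sensor pool at ``surface_ph`` (plasma membrane), the remainder at
    ``internal_ph`` (acidic compartments)."""

    f_surface: float
    surface_ph: float = 7.2
    internal_ph: float = 5.0

    def __post_init__(self):
        if not 0.0 <= self.f_surface <= 1.0:
            raise ValueError("f_surface must lie in [0, 1]")


@dataclass
class SceneParams:
    """Parameters of a simulated two-channel scene.

    Defaults emulate wide-field imaging of punctate sensor labeling:
    0.1 um pixels, vesicle radii 0.3-0.5 um, ~500 sensor copies per
    vesicle at 20 photons per copy per channel (per-pixel signal ~200
    photons over ~15 photons of background, i.e. SNR comfortably above
    10), a 0.15 um PSF, Poisson shot noise and 2-count read noise.
    """

    width_px: int = 400
    height_px: int = 400
    um_per_px: float = 0.1
    n_vesicles: int = 200
    vesicle_radius_um: tuple[float, float] = (0.3, 0.5)
    vesicle_ph_spec: float | Sequence[float] | TwoStateMix = 5.5
    devices_per_vesicle: tuple[float, float] = (500.0, 50.0)
    gain_o: float = 20.0
    gain_r: float = 20.0
    psf_sigma_um: float = 0.15
    background_o: float = 10.0
    background_r: float = 10.0
    read_noise_sd: float = 2.0
    poisson_noise: bool = True
    autofluor_density: float = 0.0  # confounder puncta per 100 um^2
    seed: int = 0

    def __post_init__(self):
        rmin, rmax = self.vesicle_radius_um
        if not (0 < rmin <= rmax):
            raise ValueError("vesicle radius range must be positive and ordered")
        if self.gain_o <= 0 or self.gain_r <= 0:
            raise ValueError("gains must be > 0")
        if min(self.background_o, self.background_r) < 0:
            raise ValueError("backgrounds must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.um_per_px <= 0 or self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("geometry must be positive")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_um / self.um_per_px


@dataclass
class ObjectTruth:
    """Ground truth for one simulated object (pre-noise, pre-background).

    ``expected_mean_o/r`` are the per-pixel photon means inside the true
    footprint before PSF blur; their ratio equals
    ``(gain_o/gain_r) * value(true_ph)`` for sensor-bearing objects.
    """

    id: int
    center: tuple[float, float]  # (row, col), px
    radius_px: float
    true_ph: float  # NaN for autofluorescent confounders
    device_count: float
    expected_mean_o: float
    expected_mean_r: float
    object_class: str  # vesicle | membrane_segment | autofluor


@dataclass
class SceneGroundTruth:
    objects: list[ObjectTruth]
    membrane_polyline: np.ndarray | None = None  # (N, 2) px, (row, col)

    def __post_init__(self):
        ids = [o.id for o in self.objects]
        if len(set(ids)) != len(ids):
            raise ValueError("object ids must be unique")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for o in self.objects:
            rows.append(
                {
                    "id": o.id,
                    "center_row": o.center[0],
                    "center_col": o.center[1],
                    "radius_px": o.radius_px,
                    "true_ph": o.true_ph,
                    "device_count": o.device_count,
                    "expected_mean_o": o.expected_mean_o,
                    "expected_mean_r": o.expected_mean_r,
                    "object_class": o.object_class,
                }
            )
        return pd.DataFrame(rows)

    def vesicles(self) -> list[ObjectTruth]:
        return [o for o in self.objects if o.object_class == "vesicle"]


# ---------------------------------------------------------------------------
# calibration fixture


@dataclass(frozen=True)
class CalibrationFixture:
    """The reference O/R-versus-pH sigmoid used by every simulation.

    Pinned by three published operating points of the sensor - a
    normalized plateau value of 0.99 at pH 5.5, 0.65 at pH 7.2, and a
    2.5-fold contrast between pH 6 and pH 8 - plus the normalization
    convention value(pH 4) = 1.
    """

    r_min: float
    r_max: float
    pka: float
    hill_n: float
    anchor_set: tuple = (
        ("value(5.5)", 0.99),
        ("value(7.2)", 0.65),
        ("value(6)/value(8)", 2.5),
        ("value(4)", 1.0),
    )

    def value(self, ph):
        return sigmoid_value(ph, self.r_min, self.r_max, self.pka, self.hill_n)

    def as_curve(self) -> CalibrationCurve:
        return CalibrationCurve(self.r_min, self.r_max, self.pka, self.hill_n, 0.0)


@lru_cache(maxsize=1)
def build_calibration_fixture() -> CalibrationFixture:
    """Solve the unique 4-parameter sigmoid satisfying the printed anchors.

    value(pH) = r_min + (r_max - r_min)/(1 + 10^(n (pH - pKa))) with
    value(5.5) = 0.99, value(7.2) = 0.65, value(6)/value(8) = 2.5, and
    value(4) = 1 (normalization convention). Solved by damped
    least-squares on the four residuals; the solution lands near
    (0.30, 1.00, 7.20, 1.08). A unit Hill coefficient cannot satisfy all
    three anchors, hence the free exponent.
    """

    def residuals(p):
        r_min, r_max, pka, n = p
        v = lambda ph: sigmoid_value(ph, r_min, r_max, pka, n)
        return [v(4.0) - 1.0, v(5.5) - 0.99, v(7.2) - 0.65, v(6.0) / v(8.0) - 2.5]

    sol = optimize.least_squares(residuals, [0.3, 1.0, 7.2, 1.1], method="lm")
    if not sol.success or np.max(np.abs(residuals(sol.x))) > 1e-6:
        raise RuntimeError("calibration fixture solver did not converge")
    r_min, r_max, pka, n = (float(x) for x in sol.x)
    return CalibrationFixture(r_min=r_min, r_max=r_max, pka=pka, hill_n=n)


# ---------------------------------------------------------------------------
# rendering helpers


def _disk_mask(shape, center, radius):
    r0, c0 = center
    rr = np.arange(max(0, int(r0 - radius) - 1), min(shape[0], int(r0 + radius) + 2))
    cc = np.arange(max(0, int(c0 - radius) - 1), min(shape[1], int(c0 + radius) + 2))
    R, C = np.meshgrid(rr, cc, indexing="ij")
    inside = (R - r0) ** 2 + (C - c0) ** 2 <= radius**2
    return R[inside], C[inside]


def _place_disks(rng, n, radius_px, shape, existing=None, max_tries_per=200):
    """Sample non-overlapping disk centers; error when density is too high."""
    centers, radii = ([], []) if existing is None else existing
    placed = []
    for i in range(n):
        r = rng.uniform(*radius_px)
        for _ in range(max_tries_per):
            row = rng.uniform(r + 1, shape[0] - r - 1)
            col = rng.uniform(r + 1, shape[1] - r - 1)
            ok = all(
                (row - rj) ** 2 + (col - cj) ** 2 > (r + rad + 1.0) ** 2
                for (rj, cj), rad in zip(centers, radii)
            )
            if ok:
                centers.append((row, col))
                radii.append(r)
                placed.append(((row, col), r))
                break
        else:
            area_frac = sum(math.pi * x**2 for x in radii) / (shape[0] * shape[1])
            raise ValueError(
                f"could not place vesicle {i + 1}/{n} without overlap after "
                f"{max_tries_per} tries; packed area fraction {area_frac:.2f} "
                "is at the density limit for this geometry"
            )
    return placed


def _apply_noise(rng, photons, params: SceneParams):
    img = photons
    if params.poisson_noise:
        img = rng.poisson(img).astype(float)
    if params.read_noise_sd > 0:
        img = img + rng.normal(0.0, params.read_noise_sd, img.shape)
    return np.clip(img, 0.0, None)


def _finish_scene(rng, o_photons, r_photons, params):
    """Blur, add background, apply the noise chain, wrap as Image2D."""
    if params.psf_sigma_px > 0:
        o_photons = ndimage.gaussian_filter(o_photons, params.psf_sigma_px)
        r_photons = ndimage.gaussian_filter(r_photons, params.psf_sigma_px)
    o_photons = o_photons + params.background_o
    r_photons = r_photons + params.background_r
    o_img = _apply_noise(rng, o_photons, params)
    r_img = _apply_noise(rng, r_photons, params)
    mk = lambda px, tag: Image2D(px, channel_tag=tag, um_per_px=params.um_per_px)
    return mk(o_img, "O"), mk(r_img, "R")


def _resolve_vesicle_phs(spec, n, rng):
    if isinstance(spec, TwoStateMix):
        n_surface = int(round(spec.f_surface * n))
        phs = np.full(n, spec.internal_ph)
        phs[rng.permutation(n)[:n_surface]] = spec.surface_ph
        return phs
    if np.isscalar(spec):
        return np.full(n, float(spec))
    phs = np.asarray(spec, dtype=float)
    if phs.shape != (n,):
        raise ValueError("per-vesicle pH list must have one entry per vesicle")
    return phs


# ---------------------------------------------------------------------------
# scene generators


def generate_vesicle_scene(
    params: SceneParams, fixture: CalibrationFixture | None = None
) -> tuple[Image2D, Image2D, SceneGroundTruth]:
    """Render a punctate two-channel scene of sensor-loaded vesicles.

    Disks are placed at random non-overlapping centers; each carries a
    Gaussian-distributed sensor copy number. Optional autofluorescent
    confounders (emulating gut-granule autofluorescence, which is bright
    at shorter wavelengths) add signal to the O channel only and carry no
    sensor.
    """
    fixture = fixture or build_calibration_fixture()
    rng = np.random.default_rng(params.seed)
    shape = (params.height_px, params.width_px)
    radius_px = tuple(r / params.um_per_px for r in params.vesicle_radius_um)

    placed = _place_disks(rng, params.n_vesicles, radius_px, shape)
    phs = _resolve_vesicle_phs(params.vesicle_ph_spec, params.n_vesicles, rng)
    mean_d, sd_d = params.devices_per_vesicle
    devices = np.clip(rng.normal(mean_d, sd_d, params.n_vesicles), 1.0, None)

    o_photons = np.zeros(shape)
    r_photons = np.zeros(shape)
    objects = []
    for i, ((center, radius), ph, dev) in enumerate(zip(placed, phs, devices)):
        rr, cc = _disk_mask(shape, center, radius)
        area = rr.size
        mean_r = dev * params.gain_r / area
        mean_o = dev * params.gain_o * float(fixture.value(ph)) / area
        o_photons[rr, cc] += mean_o
        r_photons[rr, cc] += mean_r
        objects.append(
            ObjectTruth(i, center, radius, float(ph), float(dev), mean_o, mean_r, "vesicle")
        )

    n_auto = int(round(
        params.autofluor_density
        * shape[0] * shape[1] * params.um_per_px**2 / 100.0
    ))
    if n_auto:
        existing = ([o.center for o in objects], [o.radius_px for o in objects])
        auto = _place_disks(rng, n_auto, radius_px, shape, existing=existing)
        for j, (center, radius) in enumerate(auto):
            rr, cc = _disk_mask(shape, center, radius)
            mean_o = mean_d * params.gain_o / rr.size  # sensor-bright-like in O
            o_photons[rr, cc] += mean_o
            objects.append(
                ObjectTruth(params.n_vesicles + j, center, radius,
                            float("nan"), 0.0, mean_o, 0.0, "autofluor")
            )

    o_img, r_img = _finish_scene(rng, o_photons, r_photons, params)
    return o_img, r_img, SceneGroundTruth(objects)


def generate_membrane_scene(
    params: SceneParams,
    polyline: np.ndarray,
    tube_width_um: float = 0.4,
    fixture: CalibrationFixture | None = None,
) -> tuple[Image2D, Image2D, SceneGroundTruth]:
    """Render membrane-displayed sensor as a tube along a neurite trace.

    ``params.vesicle_ph_spec`` selects the regime: a scalar pH (or a
    TwoStateMix with f_surface = 1) paints pure membrane labeling at that
    pH; a TwoStateMix with f_surface < 1 additionally scatters vesicles
    at the internal pH, with the sensor pool divided so the membrane
    holds exactly the fraction ``f_surface`` of all device copies - the
    geometry behind the two-state ensemble-ratio bound.
    """
    polyline = np.asarray(polyline, dtype=float)
    if polyline.ndim != 2 or polyline.shape[0] < 2 or polyline.shape[1] != 2:
        raise ValueError("polyline must contain at least two (row, col) points")
    shape = (params.height_px, params.width_px)
    if polyline.min() < 0 or polyline[:, 0].max() >= shape[0] or polyline[:, 1].max() >= shape[1]:
        raise ValueError("polyline must lie inside image bounds")
    seg_len = np.hypot(*np.diff(polyline, axis=0).T)
    if seg_len.sum() == 0:
        raise ValueError("polyline has zero length")

    fixture = fixture or build_calibration_fixture()
    rng = np.random.default_rng(params.seed)
    spec = params.vesicle_ph_spec
    if isinstance(spec, TwoStateMix):
        mix = spec
    elif np.isscalar(spec):
        mix = TwoStateMix(f_surface=1.0, surface_ph=float(spec))
    else:
        raise ValueError("membrane scenes take a scalar pH or a TwoStateMix")

    # tube footprint: pixels within half-width of the densely sampled trace
    dense = []
    for (p0, p1), L in zip(zip(polyline[:-1], polyline[1:]), seg_len):
        n = max(int(math.ceil(L * 4)), 2)
        t = np.linspace(0, 1, n, endpoint=False)
        dense.append(p0 + t[:, None] * (p1 - p0))
    dense = np.vstack(dense + [polyline[-1:]])
    on_trace = np.zeros(shape, dtype=bool)
    idx = np.round(dense).astype(int)
    on_trace[np.clip(idx[:, 0], 0, shape[0] - 1), np.clip(idx[:, 1], 0, shape[1] - 1)] = True
    dist = ndimage.distance_transform_edt(~on_trace)
    tube = dist <= 0.5 * tube_width_um / params.um_per_px
    tube_px = np.argwhere(tube)

    mean_d, sd_d = params.devices_per_vesicle
    o_photons = np.zeros(shape)
    r_photons = np.zeros(shape)
    objects = []

    if mix.f_surface < 1.0 and params.n_vesicles > 0:
        placed = _place_disks(rng, params.n_vesicles,
                              tuple(r / params.um_per_px for r in params.vesicle_radius_um),
                              shape)
        devices = np.clip(rng.normal(mean_d, sd_d, params.n_vesicles), 1.0, None)
        for i, ((center, radius), dev) in enumerate(zip(placed, devices)):
            rr, cc = _disk_mask(shape, center, radius)
            mean_r = dev * params.gain_r / rr.size
            mean_o = dev * params.gain_o * float(fixture.value(mix.internal_ph)) / rr.size
            o_photons[rr, cc] += mean_o
            r_photons[rr, cc] += mean_r
            objects.append(ObjectTruth(i, center, radius, mix.internal_ph,
                                       float(dev), mean_o, mean_r, "vesicle"))
        vesicle_devices = float(devices.sum())
        membrane_devices = mix.f_surface / (1.0 - mix.f_surface) * vesicle_devices
    else:
        membrane_devices = float(max(params.n_vesicles, 1) * mean_d)

    if mix.f_surface > 0.0:
        area = tube_px.shape[0]
        mem_mean_r = membrane_devices * params.gain_r / area
        mem_mean_o = membrane_devices * params.gain_o * float(fixture.value(mix.surface_ph)) / area
        o_photons[tube] += mem_mean_o
        r_photons[tube] += mem_mean_r
        centroid = tuple(tube_px.mean(axis=0))
        objects.append(ObjectTruth(len(objects), centroid,
                                   0.5 * tube_width_um / params.um_per_px,
                                   mix.surface_ph, membrane_devices,
                                   mem_mean_o, mem_mean_r, "membrane_segment"))

    o_img, r_img = _finish_scene(rng, o_photons, r_photons, params)
    return o_img, r_img, SceneGroundTruth(objects, membrane_polyline=polyline)


def generate_calibration_series(
    fixture: CalibrationFixture,
    ph_list: Sequence[float],
    noise_sd: float = 0.0,
    n_reps: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Tabulate noisy O/R draws around the fixture curve (columns
    ``ph``, ``rep``, ``o_over_r``), one row per replicate per pH."""
    ph_list = list(ph_list)
    if not ph_list:
        raise ValueError("ph_list must be non-empty")
    if any(not 3.0 <= p <= 10.0 for p in ph_list):
        raise ValueError("calibration pH values must lie in [3, 10]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for ph in ph_list:
        true = float(fixture.value(ph))
        for rep in range(n_reps):
            rows.append({"ph": ph, "rep": rep,
                         "o_over_r": true + rng.normal(0.0, noise_sd) if noise_sd else true})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# colocalization scenes


@dataclass
class ColocGroundTruth:
    """Pairing truth for a two-channel puncta scene: per red punctum its
    position along the neurite (um), pixel centers of the red and green
    puncta, and whether they are a true colocalized pair."""

    table: pd.DataFrame
    polyline: np.ndarray
    true_fraction: float
    spacing_um: float
    jitter_um: float


def generate_coloc_scene(
    n_puncta: int,
    true_coloc_fraction: float,
    spacing_um: float = 2.0,
    jitter_um: float = 0.2,
    seed: int = 0,
    um_per_px: float = 0.1,
    psf_sigma_um: float = 0.2,
    amplitude: float = 300.0,
    background: float = 10.0,
    read_noise_sd: float = 2.0,
    poisson_noise: bool = True,
) -> tuple[Image2D, Image2D, ColocGroundTruth]:
    """Lay red puncta along a neurite and give a controlled fraction a
    green partner.

    A fraction ``true_coloc_fraction`` of red puncta (count rounded) get
    a green partner displaced by at most ``jitter_um``; the remaining
    green puncta sit halfway between neighboring red puncta
    (``spacing_um / 2`` away), beyond any sensible matching tolerance.
    ``jitter_um >= spacing_um / 2`` is rejected: the ground-truth pairing
    would be ambiguous.
    """
    if not 0.0 <= true_coloc_fraction <= 1.0:
        raise ValueError("true_coloc_fraction must lie in [0, 1]")
    if jitter_um >= spacing_um / 2:
        raise ValueError("jitter_um must be < spacing_um / 2 for unambiguous truth")
    rng = np.random.default_rng(seed)

    spacing_px = spacing_um / um_per_px
    width_px = int(round((n_puncta + 1) * spacing_px))
    height_px = int(round(10.0 / um_per_px))
    mid = height_px / 2.0
    shape = (height_px, width_px)

    red_cols = spacing_px * (np.arange(n_puncta) + 1.0)
    red_centers = np.stack([np.full(n_puncta, mid), red_cols], axis=1)
    n_coloc = int(round(true_coloc_fraction * n_puncta))
    coloc_idx = np.zeros(n_puncta, dtype=bool)
    coloc_idx[rng.permutation(n_puncta)[:n_coloc]] = True

    green_centers = np.empty_like(red_centers)
    for i in range(n_puncta):
        if coloc_idx[i]:
            ang = rng.uniform(0, 2 * np.pi)
            mag = rng.uniform(0, jitter_um) / um_per_px
            green_centers[i] = red_centers[i] + mag * np.array([np.sin(ang), np.cos(ang)])
        else:
            green_centers[i] = red_centers[i] + np.array([0.0, spacing_px / 2.0])

    sigma_px = psf_sigma_um / um_per_px
    rr = np.arange(height_px)[:, None]
    cc = np.arange(width_px)[None, :]

    def render(centers):
        img = np.zeros(shape)
        for r0, c0 in centers:
            img += amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma_px**2))
        return img + background

    red = render(red_centers)
    green = render(green_centers)
    for img in (red, green):
        if poisson_noise:
            img[:] = rng.poisson(img)
        if read_noise_sd > 0:
            img += rng.normal(0.0, read_noise_sd, shape)
        np.clip(img, 0.0, None, out=img)

    table = pd.DataFrame(
        {
            "red_id": np.arange(n_puncta),
            "red_pos_um": red_cols * um_per_px,
            "red_row_px": red_centers[:, 0],
            "red_col_px": red_centers[:, 1],
            "green_row_px": green_centers[:, 0],
            "green_col_px": green_centers[:, 1],
            "colocalized": coloc_idx,
        }
    )
    polyline = np.array([[mid, 0.0], [mid, width_px - 1.0]])
    truth = ColocGroundTruth(table, polyline, true_coloc_fraction, spacing_um, jitter_um)
    mk = lambda px, tag: Image2D(px, channel_tag=tag, um_per_px=um_per_px)
    return mk(red, "R"), mk(green, "G"), truth


# ---------------------------------------------------------------------------
# writers


def write_scene(
    outdir: str | Path,
    name: str,
    o_img: Image2D,
    r_img: Image2D,
    truth: SceneGroundTruth,
    params: SceneParams | None = None,
    multipage: bool = True,
) -> dict:
    """Write a scene to disk: 16-bit TIFF channels, truth CSV, and a JSON
    scene descriptor. Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tiffs = write_tiff_channels(outdir / f"{name}.tif", [o_img, r_img], multipage=multipage)
    truth_csv = outdir / f"{name}_truth.csv"
    truth.to_dataframe().to_csv(truth_csv, index=False)
    desc = {
        "name": name,
        "channels": [o_img.channel_tag, r_img.channel_tag],
        "um_per_px": o_img.um_per_px,
        "n_objects": len(truth.objects),
    }
    if params is not None:
        p = asdict(params)
        if isinstance(params.vesicle_ph_spec, TwoStateMix):
            p["vesicle_ph_spec"] = asdict(params.vesicle_ph_spec)
        elif not np.isscalar(params.vesicle_ph_spec):
            p["vesicle_ph_spec"] = list(np.asarray(params.vesicle_ph_spec, dtype=float))
        desc["params"] = p
    desc_path = outdir / f"{name}_scene.json"
    desc_path.write_text(json.dumps(desc, indent=2, default=float))
    return {"tiffs": [str(t) for t in tiffs], "truth_csv": str(truth_csv),
            "descriptor": str(desc_path)}
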