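"""End-to-end pipeline runs: simulate, segment, quantify, report.

All randomness flows from a single run seed through a documented
stream-splitting rule (``child_seed``): each stage derives its own child
seed from the run seed and the stage name, so stages are independently
reproducible and re-running any mode with identical config and seed
reproduces all output tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.filters import threshold_otsu
from skimage.morphology import disk, erosion

from .calibration import (
    CalibrationCurve,
    PHMeasurement,
    fit_calibration,
    invert_calibration,
    normalize_to_internal_calibrator,
)
from .coloc import (
    detect_puncta_1d,
    extract_line_profile,
    pearson_roi,
    percent_colocalization,
)
from .image import Image2D, read_tiff_channels
from .rois import LineROI
from .segmentation import (
    LabelMap,
    SegmentationParams,
    extract_measurements,
    quantify_uptake,
    sauvola_threshold,
    segment_image,
    subtract_background,
    watershed_split,
    size_filter,
)
from .synthetic import (
    CalibrationFixture,
    SceneParams,
    build_calibration_fixture,
    generate_calibration_series,
    generate_coloc_scene,
    generate_vesicle_scene,
    write_scene,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "child_seed",
    "auto_cellfree_region",
    "measure_scene",
    "run_ph_pipeline",
    "run_uptake_pipeline",
    "run_coloc_pipeline",
    "run_simulate",
    "run_full",
]

logger = logging.getLogger(__name__)


def child_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific child seed from the run seed.

    Rule: ``(seed * 1_000_003 + crc32(stage)) mod 2**31``; deterministic,
    stage-name keyed, and stays below 2**31.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run.

    ``mode`` is one of simulate | segment | uptake | ph | coloc | full.
    Nested parameter blocks mirror the stage they feed. For non-simulate
    modes, ``inputs`` points at TIFF/CSV files on disk.
    """

    mode: str = "full"
    seed: int = 0
    outdir: str | None = None
    n_scenes: int = 3
    scene: SceneParams = field(default_factory=SceneParams)
    calibrator: SceneParams | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    calibration: dict = field(default_factory=dict)
    coloc: dict = field(default_factory=dict)
    uptake: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "scene" in d and not isinstance(d["scene"], SceneParams):
            d["scene"] = SceneParams(**d["scene"])
        if d.get("calibrator") is not None and not isinstance(d["calibrator"], SceneParams):
            d["calibrator"] = SceneParams(**d["calibrator"])
        if "segmentation" in d and not isinstance(d["segmentation"], SegmentationParams):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def write_resolved(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "resolved_config.yaml").write_text(
            yaml.safe_dump(json.loads(json.dumps(self.resolved(), default=str)))
        )


@dataclass
class RunReport:
    """Per-stage record of parameters, counts, summaries, and warnings."""

    mode: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def add_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "stages": self.stages,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "run_report.json").write_text(
            json.dumps(self.summary(), indent=2, default=float)
        )
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)


# ---------------------------------------------------------------------------
# shared measurement steps


def auto_cellfree_region(image: Image2D) -> np.ndarray:
    """Automated stand-in for the manually drawn adjacent cell-free area.

    Pixels well below the Otsu split (eroded to stay clear of PSF halos)
    form the background-estimation region.
    """
    thr = threshold_otsu(image.pixels)
    region = erosion(image.pixels < 0.5 * thr, disk(3))
    if not region.any():
        region = image.pixels < thr
    if not region.any():
        raise ValueError("no cell-free area found for background estimation")
    return region


def measure_scene(
    o_img: Image2D,
    r_img: Image2D,
    params: SegmentationParams,
    cellfree_region: np.ndarray | tuple[int, int, int, int] | str | None = "auto",
) -> tuple[LabelMap, list[PHMeasurement]]:
    """Segment the reference channel and recall labels onto both channels.

    Returns the label map and one PHMeasurement per vesicle ROI with
    background-subtracted mean O and R intensities. For punctate scenes
    without a contiguous cell body, a low global threshold (quarter of
    the Otsu split) restricts Sauvola selection instead of the
    largest-component cell-field rule.
    """
    if isinstance(cellfree_region, str) and cellfree_region == "auto":
        cellfree_region = auto_cellfree_region(r_img)
    if cellfree_region is not None:
        r_bg = subtract_background(r_img, cellfree_region)
        o_bg = subtract_background(o_img, cellfree_region)
    else:
        r_bg, o_bg = r_img, o_img

    low_thr = 0.25 * threshold_otsu(r_bg.pixels)
    low_mask = r_bg.pixels > low_thr
    fg = sauvola_threshold(r_bg, params, field=low_mask)
    if not fg.any():
        return LabelMap(np.zeros(r_bg.shape, dtype=np.int32), ["empty"]), []
    labels = watershed_split(fg, r_bg, params)
    labels = size_filter(labels, params)
    measurements = extract_measurements(labels, [o_bg, r_bg])
    out = [
        PHMeasurement(roi_id=m.label_id, mean_o=m.mean_intensity["O"],
                      mean_r=m.mean_intensity["R"])
        for m in measurements
        if m.mean_intensity["R"] > 0
    ]
    return labels, out


def _fit_curve_from_config(config: RunConfig, fixture: CalibrationFixture) -> CalibrationCurve:
    cal = config.calibration
    if "series_csv" in cal:
        series = pd.read_csv(cal["series_csv"])
    else:
        series = generate_calibration_series(
            fixture,
            ph_list=cal.get("ph_list", [4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0]),
            noise_sd=cal.get("noise_sd", 0.0),
            n_reps=cal.get("n_reps", 1),
            seed=child_seed(config.seed, "calibration_series"),
        )
    return fit_calibration(series, cal.get("fit_config"))


# ---------------------------------------------------------------------------
# pipelines


def run_ph_pipeline(config: RunConfig) -> RunReport:
    """Segment, ratio, normalize via the internal calibrator, invert to pH.

    Simulate mode generates ``n_scenes`` sample scenes from
    ``config.scene`` plus matching coelomocyte calibrator scenes at pH
    5.5 (``config.calibrator``); input mode reads two-channel TIFFs
    listed under ``inputs['sample']`` and ``inputs['calibrator']``.
    Emits per-ROI and summary (mean +/- s.e.m.) tables.
    """
    report = RunReport("ph", config.seed)
    fixture = build_calibration_fixture()
    curve = _fit_curve_from_config(config, fixture)
    report.add_stage("fit_calibration", **curve.to_dict())

    if config.inputs.get("sample"):
        sample_scenes = [
            tuple(read_tiff_channels(p, um_per_px=config.scene.um_per_px))
            for p in config.inputs["sample"]
        ]
        if not config.inputs.get("calibrator"):
            raise ValueError("pH pipeline requires a coelomocyte internal calibrator")
        calibrator_scenes = [
            tuple(read_tiff_channels(p, um_per_px=config.scene.um_per_px))
            for p in config.inputs["calibrator"]
        ]
    else:
        calib_params = config.calibrator or dataclasses.replace(
            config.scene, vesicle_ph_spec=5.5
        )
        sample_scenes, calibrator_scenes = [], []
        for i in range(config.n_scenes):
            sp = dataclasses.replace(
                config.scene, seed=child_seed(config.seed, f"ph_sample_{i}")
            )
            cp = dataclasses.replace(
                calib_params, seed=child_seed(config.seed, f"ph_calibrator_{i}")
            )
            o, r, _ = generate_vesicle_scene(sp, fixture)
            sample_scenes.append((o, r))
            o2, r2, _ = generate_vesicle_scene(cp, fixture)
            calibrator_scenes.append((o2, r2))
        report.add_stage("simulate", n_sample_scenes=len(sample_scenes),
                         n_calibrator_scenes=len(calibrator_scenes))

    plateau_eps = config.calibration.get("plateau_epsilon", 0.02)
    rows = []
    for i, ((o, r), (oc, rc)) in enumerate(zip(sample_scenes, calibrator_scenes)):
        _, sample_ms = measure_scene(o, r, config.segmentation)
        _, clm_ms = measure_scene(oc, rc, config.segmentation)
        if not sample_ms:
            raise ValueError(f"scene {i}: no vesicle ROIs detected")
        if not clm_ms:
            raise ValueError(f"scene {i}: no coelomocyte calibrator ROIs detected")
        normed = normalize_to_internal_calibrator(sample_ms, clm_ms, curve)
        for m in normed:
            ph, flag = invert_calibration(curve, m.normalized_o_over_r, plateau_eps)
            rows.append(
                {
                    "scene": i,
                    "roi_id": m.roi_id,
                    "mean_O": m.mean_o,
                    "mean_R": m.mean_r,
                    "O_over_R": m.o_over_r,
                    "normalized": m.normalized_o_over_r,
                    "pH": ph,
                    "flag": flag,
                }
            )
    per_roi = pd.DataFrame(rows)

    scene_means = per_roi.groupby("scene")["normalized"].mean()
    scene_ph = per_roi.groupby("scene")["pH"].mean()
    n_plateau = int((per_roi["flag"] == "at_plateau").sum())
    summary = pd.DataFrame(
        [
            {
                "n_scenes": per_roi["scene"].nunique(),
                "n_rois": len(per_roi),
                "mean_normalized_o_over_r": float(per_roi["normalized"].mean()),
                "sem_normalized_o_over_r": float(
                    scene_means.std(ddof=1) / np.sqrt(len(scene_means))
                )
                if len(scene_means) > 1
                else np.nan,
                "mean_ph": float(per_roi["pH"].mean()),
                "sem_ph": float(scene_ph.std(ddof=1) / np.sqrt(len(scene_ph)))
                if len(scene_ph) > 1
                else np.nan,
                "fraction_at_plateau": n_plateau / len(per_roi),
                "all_at_plateau": bool(n_plateau == len(per_roi)),
            }
        ]
    )
    report.tables["ph_per_roi"] = per_roi
    report.tables["ph_summary"] = summary
    report.add_stage(
        "ph_summary",
        n_rois=len(per_roi),
        mean_normalized=float(per_roi["normalized"].mean()),
        mean_ph=float(per_roi["pH"].mean()),
        fraction_at_plateau=n_plateau / len(per_roi),
    )
    if config.outdir:
        outdir = Path(config.outdir)
        config.write_resolved(outdir)
        report.write(outdir)
    return report


def run_uptake_pipeline(config: RunConfig) -> RunReport:
    """Segmentation plus per-condition uptake summary and ratio table.

    Simulate mode builds ``uptake['n_images']`` scenes per condition,
    each condition scaling ``devices_per_vesicle`` by its entry in
    ``uptake['conditions']`` (name -> relative brightness); input mode
    reads per-condition TIFF lists from ``inputs['conditions']``.
    """
    report = RunReport("uptake", config.seed)
    by_condition: dict[str, list] = {}
    if config.inputs.get("conditions"):
        for cond, paths in config.inputs["conditions"].items():
            if not paths:
                raise ValueError(f"condition {cond!r}: no input images")
            per_image = []
            for p in paths:
                channels = read_tiff_channels(p, um_per_px=config.scene.um_per_px)
                r = next((c for c in channels if c.channel_tag == "R"), channels[-1])
                o = next((c for c in channels if c.channel_tag == "O"), channels[0])
                _, labels_ms = _segment_for_uptake(o, r, config.segmentation)
                per_image.append(labels_ms)
            by_condition[cond] = per_image
    else:
        conditions = config.uptake.get("conditions", {"bright": 1.0, "dim": 0.5})
        n_images = config.uptake.get("n_images", 3)
        fixture = build_calibration_fixture()
        for cond, scale in conditions.items():
            per_image = []
            for i in range(n_images):
                mean_d, sd_d = config.scene.devices_per_vesicle
                sp = dataclasses.replace(
                    config.scene,
                    devices_per_vesicle=(mean_d * scale, sd_d * scale),
                    seed=child_seed(config.seed, f"uptake_{cond}_{i}"),
                )
                o, r, _ = generate_vesicle_scene(sp, fixture)
                _, ms = _segment_for_uptake(o, r, config.segmentation)
                per_image.append(ms)
            by_condition[cond] = per_image
        report.add_stage("simulate", conditions=list(conditions), n_images=n_images)

    table = quantify_uptake(by_condition, channel="R")
    ratios = []
    conds = list(table["condition"])
    for a in conds:
        for b in conds:
            if a < b:
                ma = float(table.loc[table["condition"] == a, "mean_intensity"].iloc[0])
                mb = float(table.loc[table["condition"] == b, "mean_intensity"].iloc[0])
                ratios.append(
                    {"condition_a": a, "condition_b": b,
                     "ratio": ma / mb if mb > 0 else np.inf}
                )
    report.tables["uptake_summary"] = table
    report.tables["uptake_ratios"] = pd.DataFrame(ratios)
    report.add_stage("quantify_uptake",
                     n_conditions=len(conds),
                     n_vesicles=int(table["n_vesicles"].sum()))
    if config.outdir:
        outdir = Path(config.outdir)
        config.write_resolved(outdir)
        report.write(outdir)
    return report


def _segment_for_uptake(o_img, r_img, params):
    labels, ms = measure_scene(o_img, r_img, params)
    from .segmentation import VesicleMeasurement  # local to avoid cycle confusion

    out = [
        VesicleMeasurement(m.roi_id, 0, (0.0, 0.0),
                           {"O": m.mean_o, "R": m.mean_r})
        for m in ms
    ]
    return labels, out


def run_coloc_pipeline(config: RunConfig) -> RunReport:
    """Line-profile colocalization per ROI with aggregate mean +/- s.e.m.

    Simulate mode draws ``coloc['n_rois']`` independent two-channel
    puncta scenes at the configured true colocalized fraction and scores
    each along its neurite; input mode reads a two-channel TIFF plus a
    line-ROI CSV (columns row0, col0, row1, col1, width_px).
    """
    report = RunReport("coloc", config.seed)
    cc = config.coloc
    tolerance = cc.get("tolerance_um", 0.5)
    min_sep = cc.get("min_sep_um", 0.5)
    rows = []
    if config.inputs.get("image"):
        channels = read_tiff_channels(
            config.inputs["image"], channel_tags=["R", "G"],
            um_per_px=config.scene.um_per_px,
        )
        if len(channels) < 2:
            raise ValueError("colocalization requires a two-channel image")
        roi_df = pd.read_csv(config.inputs["rois"])
        if roi_df.empty:
            raise ValueError("no line ROIs supplied")
        for i, r in roi_df.iterrows():
            roi = LineROI((r["row0"], r["col0"]), (r["row1"], r["col1"]),
                          int(r.get("width_px", 1)))
            rows.append(_score_roi(channels, roi, tolerance, min_sep, i))
    else:
        n_rois = cc.get("n_rois", 5)
        for i in range(n_rois):
            red, green, truth = generate_coloc_scene(
                n_puncta=cc.get("n_puncta", 100),
                true_coloc_fraction=cc.get("true_fraction", 0.8),
                spacing_um=cc.get("spacing_um", 2.0),
                jitter_um=cc.get("jitter_um", 0.2),
                seed=child_seed(config.seed, f"coloc_{i}"),
                um_per_px=config.scene.um_per_px,
            )
            p0, p1 = truth.polyline[0], truth.polyline[-1]
            roi = LineROI(tuple(p0), tuple(p1), 1)
            rows.append(_score_roi([red, green], roi, tolerance, min_sep, i))
        report.add_stage("simulate", n_rois=n_rois,
                         true_fraction=cc.get("true_fraction", 0.8))
    per_roi = pd.DataFrame(rows)
    pc = per_roi["percent_coloc"]
    summary = pd.DataFrame(
        [
            {
                "n_rois": len(per_roi),
                "mean_percent_coloc": float(pc.mean()),
                "sem_percent_coloc": float(pc.std(ddof=1) / np.sqrt(len(pc)))
                if len(pc) > 1
                else np.nan,
                "mean_pearson_r": float(per_roi["pearson_r"].mean()),
            }
        ]
    )
    report.tables["coloc_per_roi"] = per_roi
    report.tables["coloc_summary"] = summary
    report.add_stage("coloc_summary", mean_percent=float(pc.mean()))
    if config.outdir:
        outdir = Path(config.outdir)
        config.write_resolved(outdir)
        report.write(outdir)
    return report


def _score_roi(channels, roi, tolerance_um, min_sep_um, roi_id):
    red_img, green_img = channels[0], channels[1]
    profile = extract_line_profile([red_img, green_img], roi)
    red_peaks = detect_puncta_1d(
        profile.positions_um, profile.intensities[red_img.channel_tag],
        min_sep_um=min_sep_um,
    )
    green_peaks = detect_puncta_1d(
        profile.positions_um, profile.intensities[green_img.channel_tag],
        min_sep_um=min_sep_um,
    )
    result = percent_colocalization(red_peaks, green_peaks, tolerance_um)
    band = np.zeros(red_img.shape, dtype=bool)
    rr = np.clip(np.arange(int(roi.start[0]) - 3, int(roi.start[0]) + 4), 0, red_img.shape[0] - 1)
    band[rr, :] = True
    try:
        r = pearson_roi(red_img, green_img, band)
    except ValueError:
        r = np.nan
    return {
        "roi_id": roi_id,
        "n_red": result.n_red_puncta,
        "n_green": len(green_peaks),
        "n_matched": result.n_matched,
        "percent_coloc": result.percent_coloc,
        "pearson_r": r,
        "tolerance_um": tolerance_um,
    }


def run_simulate(config: RunConfig) -> RunReport:
    """Write ``n_scenes`` vesicle scenes (TIFF + truth CSV + descriptor)."""
    report = RunReport("simulate", config.seed)
    outdir = Path(config.outdir or "simulated")
    fixture = build_calibration_fixture()
    for i in range(config.n_scenes):
        sp = dataclasses.replace(config.scene, seed=child_seed(config.seed, f"scene_{i}"))
        o, r, truth = generate_vesicle_scene(sp, fixture)
        paths = write_scene(outdir, f"scene_{i:03d}", o, r, truth, sp)
        report.add_stage(f"scene_{i:03d}", **paths, n_objects=len(truth.objects))
    config.write_resolved(outdir)
    report.write(outdir)
    return report


def run_full(config: RunConfig) -> dict[str, RunReport]:
    """Simulate -> segment -> calibrate -> quantify across all readouts."""
    reports = {}
    base_out = Path(config.outdir) if config.outdir else None
    for mode, fn in (("ph", run_ph_pipeline), ("uptake", run_uptake_pipeline),
                     ("coloc", run_coloc_pipeline)):
        sub = dataclasses.replace(
            config, mode=mode,
            outdir=str(base_out / mode) if base_out else None,
        )
        reports[mode] = fn(sub)
    return reports
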