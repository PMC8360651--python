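# Methods

`vesiph` quantifies ratiometric pH measurements of DNA-nanodevice puncta in
fluorescence images of *C. elegans* tissue. The package is organised around
four computations — synthetic scene generation with ground truth, vesicle
segmentation, O/R calibration and inversion, and line-profile colocalization —
plus a pipeline layer that composes them. This note records the models, the
parameters that matter, and the choices made where the design was open.

## Ratiometric calibration model

The sensor carries a pH-sensitive dye ("O") and a pH-insensitive reference
dye ("R"). The normalized intensity ratio follows a Henderson–Hasselbalch
sigmoid with a free Hill coefficient:

    value(pH) = r_min + (r_max − r_min) / (1 + 10^(n·(pH − pKa)))

with n > 0, so the ratio decreases monotonically with pH. The *calibration
fixture* used throughout the simulations is the unique member of this family
satisfying the sensor's published operating points — normalized O/R 0.99 at
pH 5.5, 0.65 at pH 7.2, and a 2.5-fold contrast between pH 6 and pH 8 —
under the normalization convention value(pH 4) = 1. That convention is the
only one under which a monotone sigmoid satisfies all three anchors at once
(it makes the acidic plateau 0.99 rather than exactly 1). The four residual
equations are solved by Levenberg–Marquardt least squares; the solution is

    r_min ≈ 0.3026, r_max ≈ 1.0003, pKa ≈ 7.197, n ≈ 1.076,

and a unit Hill coefficient provably cannot satisfy all three anchors.
Fixture solving is deterministic; non-convergence is a hard failure.

Curve fitting to measured series (`fit_calibration`) uses bounded
least-squares (r_min ≥ 0, n ∈ [0.5, 4]) from a fixed multi-start grid
(pKa ∈ {5.5, 6.0, …, 8.5} × n ∈ {0.5, 1, 2}), so fits are deterministic with
no seed dependence. Fits need ≥ 4 distinct pH points and fail loudly when
the RMS residual exceeds a configurable ceiling (default 0.2).

### Internal calibrator

Absolute O/R values in a specimen depend on channel gains, exposure, and
optics. They are mapped onto the calibration axis with an internal
calibrator: coelomocyte lysosomes, whose lumen sits at pH 5.5. The mean raw
O/R over calibrator ROIs is assigned the curve value at pH 5.5 and the same
multiplicative factor rescales every measurement. Any channel-wide gain
applied equally to sample and calibrator therefore cancels exactly; this is
tested to < 1e-6 in reported pH.

### Inversion and the plateau

The sigmoid admits an analytic inverse on its open range:

    pH = pKa + log10((r_max − v) / (v − r_min)) / n.

Below ~pH 6 the sensor saturates — every acidic compartment reports the
same maximal ratio, a deliberately "digital" readout of
surface-versus-internalized state. Inverting near the plateau is numerically
unstable and physically meaningless, so ratios within `plateau_epsilon`
(default 0.02) of r_max are flagged `at_plateau` and reported as pH ≤ 6 with
the point estimate clamped to 6.0. Ratios below value(pH 9) are flagged
`above_range`. Elsewhere the round trip invert(value(pH)) = pH holds to
< 1e-9.

### Two-state mixture bound

With equal per-device R emission, an ensemble with fraction f of sensor at
the surface ratio r_s and 1 − f at the internal ratio r_i reads
f·r_s + (1 − f)·r_i. The largest surface fraction compatible with an
ensemble ratio within ε of the pure internal value is

    f_surface_max = min(1, ε / (r_i − r_s)),    f_internal_min = 1 − f_surface_max.

For the canonical inputs (r_s = 0.65, r_i = 0.99, ε = 0.03) this gives
f_surface_max = 0.0882, i.e. ≥ 91.2% internalized, verified against a
brute-force grid over f at 1e-5 resolution. A bound of 7%/93% sometimes
quoted for these same inputs cannot be produced by this linear
equal-emission model under any rounding; it would require a different,
unstated mixture weighting. The package implements the linear model and
reports 8.8%.

## Synthetic scenes

The generator is the package's substitute for specimens: every downstream
stage is validated on scenes whose per-object truth (position, radius, pH,
sensor copy number, expected channel means) is known exactly.

Photometric model: each object carries `device_count` sensor copies; total
photons are `device_count × gain_r` in R and
`device_count × gain_o × value(pH)` in O, spread uniformly over the object
footprint, blurred by a Gaussian PSF, offset by a constant background, then
Poisson shot noise and additive Gaussian read noise are applied (the
standard CCD/EMCCD chain; images are quantized to 16 bits only on write).
With the PSF off, photon conservation is exact and testable; with noise off,
per-object mean O / mean R equals (gain_o/gain_r)·value(pH) to machine
precision.

Defaults (all exposed on `SceneParams`): 400×400 px at 0.1 µm/px; 200
vesicles of radius 0.3–0.5 µm; 500 ± 50 devices per vesicle; 20 photons per
device per channel; PSF σ 0.15 µm; background 10 counts; read noise σ 2.
These put per-pixel object signal near 200 photons over ~15 counts of
background noise, i.e. SNR comfortably above 10 — a bright, well-sampled
wide-field regime. Acquisition bit depth and camera gain are declared
defaults, not inferred from any source.

Scene regimes: (i) vesicle scenes with constant, per-vesicle, or two-state
pH assignment, optionally with autofluorescent confounder puncta that are
bright in the short-wavelength channel and dark in R (gut-granule
autofluorescence) and carry no sensor; (ii) membrane scenes painting the
sensor as a tube (default width 0.4 µm) along a neurite polyline at a
surface pH, where a `TwoStateMix` divides the device pool so the membrane
holds exactly fraction f of all copies — making the ensemble-ratio mixture
linearity exact pre-noise; (iii) two-channel colocalization scenes that
place red puncta at fixed spacing along a neurite and give exactly
round(f·n) of them a green partner within `jitter_um`, parking the rest
half a spacing away (generation refuses jitter ≥ spacing/2, where ground
truth would be ambiguous); (iv) calibration series tables with Gaussian
noise around the fixture curve.

All randomness comes from `numpy.random.default_rng(seed)`; identical
parameters and seed reproduce scenes byte-for-byte. What the generator does
*not* emulate: 3-D structure, anatomical context, spatially varying
background, optical aberrations beyond the Gaussian PSF, bleaching, or
chromatic misregistration (an optional integer channel shift is the only
registration degree of freedom). Passing tests therefore demonstrate
correctness of the computations under a clean image-formation model, not
robustness to every real-microscope artifact.

## Segmentation

Segmentation runs on the reference (R) channel and the label regions are
recalled onto the O channel, so both means come from identical geometry —
which is also why per-ROI O/R is insensitive to the exact mask boundary.

Stages: (1) background subtraction by the mean of a cell-free region,
clipped at zero; (2) an optional low "field" threshold restricting analysis
to the cell (fractions ≤ 1 are relative to the image maximum; the largest
connected component is kept); (3) Sauvola adaptive thresholding,
T = m·(1 + k·(s/R_dyn − 1)) over a w×w window, with **truncated** windows at
borders (no padding — padding invents intensities) and **strict** inequality
(constant images yield empty foreground); (4) watershed on the inverted
Euclidean distance transform, seeded at distance-transform maxima separated
by ≥ `watershed_min_sep_px` (default 3 px, ties broken in raster order);
(5) size filtering to [4, 400] px with contiguous renumbering in raster
order (idempotent); (6) optional declarative manual corrections
(delete/merge/add-polygon) applied in file order with an audit trail.

Sauvola parameters default to the classical k = 0.2 and w = 15 px. The
dynamic-range constant R_dyn defaults to half the image's own dynamic range
rather than a fixed half-dtype-maximum: photon-count images have no natural
dtype scale, and this choice makes the entire chain invariant under
channel-wide gain factors (set `sauvola_rdyn=32767.5` to reproduce the
fixed 16-bit convention). The implementation uses integral images and is
pixel-identical to direct per-pixel evaluation, which the tests enforce
against a double-loop oracle on random images.

The pipeline's automated stand-ins for manual steps: the cell-free
background region defaults to pixels well below the Otsu split, eroded by a
3-px disk to stay clear of PSF halos; on punctate scenes without a
contiguous cell body, a low global threshold (quarter of the Otsu value)
replaces the largest-component field rule, since puncta form many
components. Both are configurable; neither exact manual value is derivable
from first principles, so both are declared defaults.

Uptake summaries report, per condition, the grand mean of per-vesicle mean
intensities, the s.e.m. across animals (one image = one worm), and vesicle
and worm counts; a condition with zero detected vesicles reports mean 0
with a warning rather than failing.

## Colocalization

Profiles are sampled bilinearly at 1-px steps along a line ROI, averaged
over `width_px` perpendicular offsets. Puncta are detected as 1-D local
maxima with a prominence floor (default 20% of the profile's dynamic range,
robust to baseline drift) and a minimum separation (default 0.5 µm).
Percent colocalization is asymmetric by definition — red puncta with a
green partner, out of all red puncta — using greedy one-to-one matching by
increasing pair distance with a default tolerance of 0.5 µm (≈ punctum
radius at 60× magnification). Greedy matching guarantees no green punctum
is claimed twice; a symmetric variant is available but not the default.
Pearson's coefficient over a pixel mask is provided for area-based
colocalization.

## Pipeline and reproducibility

All randomness in a run flows from one seed via
`child_seed(seed, stage) = (seed·1000003 + crc32(stage)) mod 2^31`, so each
stage (every scene, the calibration series) is independently reproducible.
Re-running a mode with identical config and seed reproduces all output
tables byte-for-byte, and every run writes its fully resolved configuration
beside its outputs.

Problem sizes used by the packaged analyses and checks: calibration fitting
on an 11-point noiseless series; lysosome-plateau quantification on 10
seeded scenes of 200 vesicles each (with matched calibrator scenes); pH
parameter recovery on 150-vesicle scenes at pH 6.8/7.2/7.6; colocalization
recovery on 20 scenes of 100 puncta at a true fraction of 0.8; uptake on
two conditions × 5 images × 150 vesicles. These sizes give stable estimates
(s.e.m. well inside the tolerances checked) while keeping a full run in
minutes on one core.

## Known limitations

- Strictly 2-D; the focal plane is assumed chosen upstream.
- Per-ROI pH only; no per-pixel pH maps.
- The plateau makes pH below ~6.3 unrecoverable by design (reported as
  pH ≤ 6); estimates above ~8.5 are flagged rather than trusted.
- The mixture bound assumes equal per-device R emission in both states.
- Subpixel channel registration, Manders coefficients, and randomized
  (Costes-style) colocalization significance are out of scope.
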