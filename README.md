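# vesiph

Quantitative image analysis for ratiometric, DNA-nanodevice-based pH
sensing in *C. elegans* tissue: vesicle segmentation of fluorescent puncta,
O/R calibration-curve fitting and inversion with an internal calibrator, a
two-state surface-versus-internalized mixture bound, uptake quantification,
and line-profile colocalization — all exercised end-to-end on synthetic
two-channel microscopy scenes with exact ground truth.

It is written for microscopists and quantitative biologists who image a
two-dye sensor (a pH-sensitive "O" dye and a pH-insensitive reference "R"
dye) in worm intestine, neurons, or coelomocytes and need reproducible
per-vesicle numbers rather than by-hand ImageJ workflows.

## The model

The sensor's normalized intensity ratio follows a Henderson–Hasselbalch
sigmoid with a free Hill coefficient,

    O/R(pH) = r_min + (r_max − r_min) / (1 + 10^(n·(pH − pKa))),

fitted by deterministic multi-start least squares and inverted
analytically. In-specimen ratios are rescaled onto the calibration axis via
an internal calibrator (coelomocyte lysosomes, pH 5.5). The sensor
saturates below ~pH 6 — every acidic compartment reports the same maximal
ratio of 0.99 — so ratios near the plateau are reported as pH ≤ 6, and the
two observable states (≈0.65 at the cell surface, ≈0.99 in compartments)
yield a bound on the surface-resident fraction:
f_surface ≤ ε / (r_internal − r_surface) for ensemble error ε.

Segmentation reproduces the classic punctate-organelle chain on the R
channel: cell-free background subtraction, a low field threshold, Sauvola
adaptive thresholding T = m·(1 + k·(s/R_dyn − 1)) with truncated edge
windows, watershed splitting on the distance transform, and size filtering;
labels are recalled onto the O channel so both means share one geometry.
See `docs/methods.md` for the full account.

## Worked example

Run the calibration analysis:

```sh
python analysis/01_calibration_fixture.py
```

```
Calibration fixture (anchor-pinned sigmoid):
  r_min=0.3026  r_max=1.0003  pKa=7.1967  n=1.0764
Refit from sampled series:
  value(5.5) = 0.9900   (plateau; expect 0.99)
  value(7.2) = 0.6500   (membrane; expect 0.65)
  fold change pH 8 -> 6 = 2.5000   (expect 2.5)
  invert(0.65) = pH 7.200 [in_range]
Two-state mixture bound at ensemble error 0.03:
  f_surface_max = 0.0882  f_internal_min = 0.9118
```

The sigmoid pinned by the three operating points has its pKa at 7.20, a
0.65 ratio inverts to pH 7.2 (a membrane-displayed sensor at extracellular
pH), and at an ensemble error of 0.03 at most 8.8% of the sensor can sit on
the plasma membrane — at least 91.2% is internalized.

Then the full pipeline over the three simulated imaging regimes:

```sh
python analysis/02_ph_quantification.py
```

```
neuron_internalized_ph5.5: normalized O/R = 0.991 +/- 0.001 (s.e.m., 600 ROIs over 3 scenes); pH = 5.98; 75% at plateau
membrane_displayed_ph7.2: normalized O/R = 0.651 +/- 0.001 (s.e.m., 600 ROIs over 3 scenes); pH = 7.20; 0% at plateau
coelomocyte_lysosome_ph5.5: normalized O/R = 0.991 +/- 0.001 (s.e.m., 600 ROIs over 3 scenes); pH = 5.98; 75% at plateau
```

Acidic-compartment scenes sit at the 0.99 plateau (reported as pH ≤ 6);
membrane scenes read 0.65 → pH 7.2. `analysis/03_uptake.py` and
`analysis/04_colocalization.py` run the uptake (two-fold contrast recovered
as 1.99×) and colocalization (true 80% recovered as 80.0 ± 0.0%) readouts.
All tables land in `results/`.

The same computations are available as a CLI
(`vesiph simulate|segment|uptake|ph|coloc|full --config cfg.yaml --seed N
--out DIR`) for running on real TIFF/CSV inputs.

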