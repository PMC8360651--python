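#!/usr/bin/env python
"""Derive the reference O/R-versus-pH calibration and its consequences.

Solves the 4-parameter sigmoid pinned by the sensor's three published
operating points (normalized O/R 0.99 at pH 5.5, 0.65 at pH 7.2, and a
2.5-fold contrast between pH 6 and pH 8, normalized to 1 at pH 4),
refits it from a sampled series as the pipeline would, and derives the
two-state surface-versus-internalized mixture bound at the experimental
error of 0.03.

Writes results/calibration_curve.json and results/calibration_series.csv.
"""

import json
from pathlib import Path

from vesiph import (
    build_calibration_fixture,
    fit_calibration,
    fold_change,
    generate_calibration_series,
    invert_calibration,
    surface_fraction_bound,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    fixture = build_calibration_fixture()
    print("Calibration fixture (anchor-pinned sigmoid):")
    print(f"  r_min={fixture.r_min:.4f}  r_max={fixture.r_max:.4f}  "
          f"pKa={fixture.pka:.4f}  n={fixture.hill_n:.4f}")

    series = generate_calibration_series(
        fixture, [4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0]
    )
    series.to_csv(OUT / "calibration_series.csv", index=False)
    curve = fit_calibration(series)
    print("Refit from sampled series:")
    print(f"  value(5.5) = {curve.value(5.5):.4f}   (plateau; expect 0.99)")
    print(f"  value(7.2) = {curve.value(7.2):.4f}   (membrane; expect 0.65)")
    fc = fold_change(curve, 8.0, 6.0)
    print(f"  fold change pH 8 -> 6 = {fc:.4f}   (expect 2.5)")
    ph, flag = invert_calibration(curve, 0.65)
    print(f"  invert(0.65) = pH {ph:.3f} [{flag}]")

    bound = surface_fraction_bound(
        r_surface=curve.value(7.2), r_internal=curve.value(5.5), epsilon=0.03
    )
    print("Two-state mixture bound at ensemble error 0.03:")
    print(f"  f_surface_max = {bound.f_surface_max:.4f}  "
          f"f_internal_min = {bound.f_internal_min:.4f}")

    payload = curve.to_dict()
    payload["anchors"] = {k: v for k, v in fixture.anchor_set}
    payload["fold_change_8_to_6"] = fc
    payload["invert_0.65"] = ph
    payload["mixture_bound"] = {
        "f_surface_max": bound.f_surface_max,
        "f_internal_min": bound.f_internal_min,
        "epsilon": bound.epsilon,
    }
    (OUT / "calibration_curve.json").write_text(json.dumps(payload, indent=2))
    print(f"Wrote {OUT / 'calibration_curve.json'}")


if __name__ == "__main__":
    main()
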