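#!/usr/bin/env python
"""Stage 4: displacement-scan analysis and the intensity-loss estimate.

Runs the full transient-absorption pipeline on synthetic jet scans for
the two experimental regimes: a clean jet whose excitation profile
matches the 99 um pump-probe overlap, and a crystal-loaded jet whose
profile is scattering-broadened to 144 um.  Each scan carries realistic
noise and 20% jet-miss outlier spectra; the pipeline pools by band and
delay window, applies the 50% median-rejection average, subtracts the
negative-delay background, and fits ESA + GSB profiles globally with a
shared centre and FWHM.  The fitted width against the overlap width gives
the broadening and the (upper-bound) peak excitation-intensity loss.

Writes results/ta_scan_fits.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from jetlight import (
    SynthTAConfig,
    build_displacement_profile,
    calibrate_excitation_fwhm,
    global_gaussian_fit,
    intensity_loss_estimate,
    synth_ta_scan,
)

OVERLAP_FWHM_UM = 99.0  # pump-probe overlap width (85 um pump, 20 um probe)

CASES = {  # label -> (target profile FWHM um, contamination-tail fraction)
    "clean jet (LCP + dye)": (99.0, 0.0),
    "crystal-loaded jet": (144.0, 0.3),
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parents[1] / "results")
    args = ap.parse_args()

    rows = []
    for i, (label, (target, tail)) in enumerate(CASES.items()):
        core = calibrate_excitation_fwhm(target, 20.0, tail_fraction=tail)
        cfg = SynthTAConfig(
            excitation_fwhm_um=core, tail_fraction=tail,
            probe_fwhm_um=20.0, noise_sigma=0.0008, outlier_prob=0.2,
            seed=args.seed + i)
        result = synth_ta_scan(cfg)
        profile = build_displacement_profile(result.records)
        fit = global_gaussian_fit(profile)
        est = intensity_loss_estimate(OVERLAP_FWHM_UM, fit.fwhm_um)
        rows.append({
            "case": label,
            "true_profile_fwhm_um": result.true_profile_fwhm_um,
            "fitted_fwhm_um": fit.fwhm_um,
            "fitted_center_um": fit.center_um,
            "esa_amplitude": fit.amplitude["ESA"],
            "gsb_amplitude": fit.amplitude["GSB"],
            "overlap_fwhm_um": OVERLAP_FWHM_UM,
            "broadening_pct": 100.0 * est.broadening,
            "peak_loss_pct": 100.0 * est.peak_loss,
            "seed": cfg.seed,
        })

    table = pd.DataFrame(rows)
    args.out.mkdir(exist_ok=True)
    table.to_csv(args.out / "ta_scan_fits.csv", index=False)

    print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    broad = table.iloc[1]
    print(f"\nThe crystal-loaded jet's dA profile fits to "
          f"{broad['fitted_fwhm_um']:.0f} um FWHM vs the "
          f"{OVERLAP_FWHM_UM:.0f} um overlap expectation: "
          f"{broad['broadening_pct']:.0f}% broadening, i.e. at most a "
          f"{broad['peak_loss_pct']:.0f}% drop in peak excitation "
          "intensity if the scattered light is fully redistributed along "
          "the jet.  The clean jet shows no significant broadening.")
    print(f"Wrote {args.out / 'ta_scan_fits.csv'}")


if __name__ == "__main__":
    main()
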