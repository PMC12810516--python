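#!/usr/bin/env python
"""Stage 3: Monte Carlo fluence in the jet for three scattering regimes.

Simulates the 150 um jet inside a 200 um host layer hit side-on by an
85 x 85 um FWHM Gaussian beam, for cylinder total scattering coefficients
0.1 (negligible), 9.8 (cellulose gel + crystals) and 53.8 mm^-1 (PTFE
grease + crystals), with mu_a = 1 mm^-1, g = 0.9, n = 1.4.  The jet is
sliced into discs along its axis and the disc-averaged fluence tabulated.
The finding: the focal-disc fluence barely drops even at the highest
scattering, but the tails along the jet -- pump light contaminating
nominally unpumped sample -- grow by orders of magnitude.

Default 3x10^5 photons per case (a desk-scale run; raise --photons for
production).  Writes results/mc_disc_profiles.csv and
results/mc_summary.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from jetlight import (
    MCConfig,
    MCGeometry,
    MediumMC,
    axial_fluence_profile,
    run_mc,
)
from jetlight.ta import estimate_fwhm

CASES = {  # label -> cylinder total scattering coefficient, mm^-1
    "negligible": 0.1,
    "HEC + crystals": 9.8,
    "Super Lube + crystals": 53.8,
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--photons", type=int, default=300_000)
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parents[1] / "results")
    args = ap.parse_args()

    profiles, summary = {}, []
    for i, (label, mu_s) in enumerate(CASES.items()):
        cfg = MCConfig(
            geometry=MCGeometry(slab_thickness_um=200.0,
                                cylinder_diameter_um=150.0),
            slab=MediumMC(mu_a=0.1, mu_s=0.1, g=0.0, n=1.0),
            cylinder=MediumMC(mu_a=1.0, mu_s=mu_s, g=0.9, n=1.4),
            n_photons=args.photons,
            seed=args.seed + i,
        )
        tally = run_mc(cfg)
        y, prof = axial_fluence_profile(tally, 150.0)
        profiles[label] = prof
        summary.append({
            "case": label,
            "mu_s_mm^-1": mu_s,
            "focal_disc_fluence": prof[np.abs(y) < 20.0].mean(),
            "tail_fluence_sum": prof[np.abs(y) > 150.0].sum(),
            "profile_fwhm_um": estimate_fwhm(y, prof),
            "energy_closure": tally.energy_closure,
            "n_photons": args.photons,
            "seed": cfg.seed,
        })

    args.out.mkdir(exist_ok=True)
    table = pd.DataFrame({"y_um": y, **profiles})
    table.to_csv(args.out / "mc_disc_profiles.csv", index=False)
    s = pd.DataFrame(summary)
    s.to_csv(args.out / "mc_summary.csv", index=False)

    print(s.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    p = s["focal_disc_fluence"]
    t = s["tail_fluence_sum"]
    drop = max(0.0, 100 * (1 - p.iloc[2] / p.iloc[0]))
    print(f"\nFocal-disc fluence drops only {drop:.1f}% "
          f"from negligible to strongest scattering, while tail light "
          f"grows {t.iloc[2] / t.iloc[0]:.0f}-fold: scattering "
          "redistributes pump light along the jet (light contamination) "
          "far more than it removes it from the focus.")
    print(f"Wrote {args.out / 'mc_disc_profiles.csv'} and mc_summary.csv")


if __name__ == "__main__":
    main()
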