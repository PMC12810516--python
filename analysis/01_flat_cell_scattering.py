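#!/usr/bin/env python
"""Stage 1: scattering coefficients of jetting media from flat-cell
transmittance.

Generates synthetic integrating-sphere transmittance tables for the six
measured jetting media (flat cells of 22, 100, 200 and 500 um path
length, 1% multiplicative noise) plus the one absorbing fixture
(chromophore-containing crystals, S and K both free), fits each with the
two-flux model, and tabulates recovered vs true coefficients.

Writes results/km_fits.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from jetlight import KMCoefficients, SynthKMConfig, km_fit, synth_transmittance

MEDIA_S = {  # backward-scattering coefficients at 515 nm, mm^-1
    "LCP": 0.089,
    "LCP + thaumatin crystals": 0.204,
    "HEC": 0.016,
    "HEC + thaumatin crystals": 0.371,
    "Super Lube": 0.185,
    "Super Lube + thaumatin crystals": 2.344,
}
ABSORBER = ("LCP + FAP crystals (470 nm)", 0.399, 0.585)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parents[1] / "results")
    args = ap.parse_args()

    rows = []
    for i, (name, S_true) in enumerate(sorted(MEDIA_S.items())):
        cfg = SynthKMConfig(truth=KMCoefficients(S_true, 0.0),
                            noise_sigma=0.01, seed=args.seed + i,
                            sample=name)
        fit = km_fit(synth_transmittance(cfg), fix_K_to_zero=True)
        rows.append({"sample": name, "S_true": S_true, "K_true": 0.0,
                     "S_fit": fit.optics.S, "K_fit": 0.0, "K_fixed": True,
                     "converged": fit.converged})
    name, S_true, K_true = ABSORBER
    cfg = SynthKMConfig(truth=KMCoefficients(S_true, K_true),
                        noise_sigma=0.01, seed=args.seed + 99, sample=name,
                        wavelength_nm=470.0)
    fit = km_fit(synth_transmittance(cfg), fix_K_to_zero=False)
    rows.append({"sample": name, "S_true": S_true, "K_true": K_true,
                 "S_fit": fit.optics.S, "K_fit": fit.optics.K,
                 "K_fixed": False, "converged": fit.converged})

    table = pd.DataFrame(rows)
    args.out.mkdir(exist_ok=True)
    table.to_csv(args.out / "km_fits.csv", index=False)

    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    strong = table[(table["S_true"] >= 0.1) & table["K_fixed"]]
    worst = (strong["S_fit"] / strong["S_true"] - 1).abs().max()
    print(f"\nScattering-only fits with S >= 0.1 mm^-1 recover S within "
          f"{100 * worst:.0f}% at 1% transmittance noise; weaker media "
          "(e.g. S = 0.016 mm^-1 transmits > 99% through every cell) sit "
          "at the noise floor, and the jointly fitted absorbing sample is "
          "weakly identified on four path lengths (S and K trade off "
          "against a pure-absorption model).")
    print(f"Wrote {args.out / 'km_fits.csv'}")


if __name__ == "__main__":
    main()
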