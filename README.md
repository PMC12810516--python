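# jetlight

How much pump-laser light does a protein microcrystal inside a
high-viscosity extrusion (HVE) jet actually receive?  Time-resolved
serial crystallography excites microcrystals with a focused pump pulse
while they ride a viscous jet (lipidic cubic phase, cellulose gel, PTFE
grease) into the X-ray beam.  Scattering by the medium and the crystals
has been blamed for intensity losses anywhere from 20% to 99% — a
disagreement with direct consequences for how hard samples get pumped.
`jetlight` implements the complete computational chain for settling the
question:

1. **`jetlight.km`** — Kubelka–Munk two-flux radiative transfer in a
   slab: transmittance `T(d) = b/(a·sinh(bSd) + b·cosh(bSd))` with
   `a = (S+K)/S`, `b = √(a²−1)`, internal flux profiles I(x), J(x), and
   joint fitting of the backward-scattering coefficient S and absorption
   coefficient K (mm⁻¹) from multi-path-length integrating-sphere
   transmittance.
2. **`jetlight.mc`** — seeded Monte Carlo photon transport in the jet
   geometry: Gaussian beam onto an infinite cylinder (n = 1.4, g = 0.9
   Henyey–Greenstein) inside a thin host slab, discrete absorption
   weighting, Fresnel/total-internal-reflection at the jet surface, and
   a voxel track-length fluence tally with disc-averaged axial profiles.
3. **`jetlight.ta`** — pump–probe displacement-scan analysis:
   ΔA = −log₁₀(I_pumped/I_unpumped), pooling by spectral band (ESA
   435–445 nm, GSB 615–625 nm) and delay window (10–50 ps vs −10…−1 ps),
   median-filtered averaging with 50% rejection, global Gaussian fits
   with shared centre/FWHM, the pump–probe overlap integral, and the
   broadening → peak-intensity-loss conversion.
4. **`jetlight.synthetic`** — seeded generators for all three input
   classes (transmittance tables, displacement scans with jet-miss
   outliers, beam-profiler traces) that expose their ground truth, so
   every pipeline test is a parameter-recovery test.
5. **`jetlight.io` / `jetlight.cli`** — delimited-text schemas with unit
   handling (µm/nm in files, mm/mm⁻¹ internally), JSON reports, tally
   containers, run manifests, and the `jetlight` command-line tool
   (`km-fit`, `km-profile`, `mc-run`, `ta-analyze`, `synth`).

The `analysis/` directory holds the four numbered drivers that walk the
full study: flat-cell coefficient fits → internal flux in a scattering
slab → Monte Carlo fluence in the jet → displacement-scan loss estimate.
Each writes its tables under `results/`.

## Worked example

Internal light intensity in a 150 µm layer of the strongest-scattering
jetting medium measured (PTFE grease loaded with thaumatin crystals,
S = 2.344 mm⁻¹) with a representative absorption K = 1 mm⁻¹:

```python
>>> from jetlight import KMCoefficients, km_flux_profile
>>> prof = km_flux_profile(KMCoefficients(S=2.344, K=1.0), d=0.150, n_points=1001)
>>> round(float(prof.total[500]), 4)   # I + J at the slab centre
0.9162
>>> round(float(prof.total[0]), 4)     # entrance face: MORE than incident
1.2277
>>> round(float(prof.I[-1]), 4)        # transmittance of the slab
0.6341
```

Even under strong scattering the central layer keeps 92% of the
incident intensity — scattering redistributes light (the entrance face
sees 123%) far more than it removes it.  The same conclusion at full
geometric fidelity, from `analysis/03_jet_monte_carlo.py` (3×10⁵
photons per case):

```
                 case  mu_s_mm^-1  focal_disc_fluence  tail_fluence_sum  profile_fwhm_um
           negligible         0.1            7.47e-05          1.74e-06             84.2
       HEC + crystals         9.8            7.46e-05          0.000102             87.6
Super Lube + crystals        53.8            7.47e-05          0.000339              101
```

The focal-disc fluence is essentially unchanged across a 500-fold range
of scattering coefficient, while the light spilled beyond ±150 µm along
the jet grows ~200-fold — the real cost of scattering is *light
contamination* of sample that will be probed at other time delays, not
loss of excitation at the focus.

The experimental displacement scan quantifies the same effect in a real
jet: a crystal-loaded jet broadens the ΔA profile from the 99 µm
pump–probe overlap expectation to 144 µm, and

```python
>>> from jetlight import intensity_loss_estimate
>>> est = intensity_loss_estimate(overlap_fwhm_um=99.0, measured_fwhm_um=144.0)
>>> round(est.broadening, 4), round(est.peak_loss, 4)
(0.4545, 0.3125)
```

a 45% broadening, i.e. at most a ~31% drop in peak excitation intensity
— an upper bound that the Monte Carlo stage shows is itself generous.
Scattering cannot turn a nonlinear pump energy into a linear one.

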