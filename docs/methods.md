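# Methods

`jetlight` quantifies how much pump-laser light a protein microcrystal
embedded in a high-viscosity extrusion (HVE) jet actually receives.  The
question matters because scattering by the jetting medium (lipidic cubic
phase, hydroxyethyl-cellulose gel, PTFE grease) and by the embedded
crystals has been invoked to justify pump energies far above the linear
excitation regime.  The package implements three complementary models of
the same physics at increasing geometric fidelity: a two-flux slab model,
a Monte Carlo simulation of the actual cylinder-in-slab jet geometry, and
the analysis of a pump–probe displacement-scan experiment that measures
the excitation profile along a real jet.

## 1. Two-flux (Kubelka–Munk) slab model

### Model

Diffuse light in a plane-parallel slab is split into a forward flux
I(x) and a backward flux J(x) coupled by

    dI/dx = −(S + K) I + S J
    dJ/dx = +(S + K) J − S I ,

with S (mm⁻¹) the backward-scattering coefficient for diffuse light (the
probability per unit path of a direction-reversing scattering event) and
K (mm⁻¹) the diffuse absorption coefficient.  With I(0) = 1 and
J(d) = 0 the transmittance is

    T(d) = b / (a·sinh(bSd) + b·cosh(bSd)),
    a = (S + K)/S,  b = √(a² − 1),

and the internal fluxes are

    I(x) = [a·sinh(bS(d−x)) + b·cosh(bS(d−x))] / D,
    J(x) = sinh(bS(d−x)) / D,     D = a·sinh(bSd) + b·cosh(bSd).

These closed forms are pinned two ways in the tests: against direct
boundary-value integration of the ODE system (matrix exponential, ≤1e−6
absolute over random parameter draws), and against the worked result that
a 150 µm slab with S = 2.344 mm⁻¹ and K = 1.0 mm⁻¹ retains 92% of the
incident intensity at its central layer.  A variant functional form that
failed either check would be rejected.

Two qualitative consequences the tests also assert: the total intensity
I + J at the entrance face *exceeds* 1 for a strong scatterer (back-
scattered light adds to the undepleted forward flux — 1.228 for the
parameters above), and with K = 0 the depth-mean of I + J is exactly 1
for any S: scattering redistributes light between directions without
changing the mean photon flux density.  A related stacking identity,
T(2d) = T(d)²/(1 − R(d)²) ≥ T(d)², is asserted as a property test; the
inequality direction follows from inter-layer back-reflection.

### Numerical choices

* K = 0 and S = 0 limits are evaluated by their analytic limit
  expressions, T = 1/(1 + Sd) and T = e^{−Kd}, never by the general form
  (which degenerates to 0/0).  Inputs where K > 0 but K/S is below double
  round-off (so b collapses to exactly 0) are routed to the conservative
  limit; the relative error is at machine-epsilon level.
* Path lengths are micrometres in files and millimetres internally;
  coefficients are always mm⁻¹ (the units of the measured coefficient
  table).  Conversions live only in the I/O layer.
* Flux profiles are returned on a uniform grid; the depth-mean uses the
  trapezoid rule on that grid.

### Coefficient fitting

`km_fit` minimizes Σᵢ (T_model(dᵢ) − T_obs,i)² with S (and optionally K)
bounded non-negative (lmfit/least-squares).  Weighting is uniform — the
measured transmittances carry no stated per-point uncertainties.  The
default fixes K = 0, appropriate for media with no absorber at the probe
wavelength; a single record then inverts exactly to S = (1/T − 1)/d.
The initial guess is that inversion applied to the mean record.

A caveat established by a simulation study in the tests: the joint (S, K)
fit on the four standard flat-cell path lengths (22, 100, 200, 500 µm) is
nearly degenerate with a pure-absorption model T = e^{−K′d}, K′ ≈ S + K.
At 1% transmittance noise roughly a third of replicate fits collapse to
S ≈ 0, and the *median* recovered pair is biased by only a few percent —
but the median of 100 replicates still has ±16% sampling spread.  The
recovery test therefore uses 2000 replicates, where the median's own
sampling error (~3.5%) is small against the 10% recovery band.  Users
fitting absorbing samples should add shorter/longer path lengths or an
independent absorption measurement rather than trust a single
four-point joint fit.

The calibrated path length is the caller's responsibility (the nominal
10 µm demountable cell in the measured dataset is actually 22 µm); no
automatic correction is attempted.  The model treats the incident light
as diffuse, per the two-flux assumptions; collimated-beam corrections
(four-flux / DRS-style models) are deliberately out of scope, and the
total scattering coefficients they produce enter only as Monte Carlo
inputs below.

## 2. Monte Carlo photon transport in jet geometry

### Geometry and physics

An infinite circular cylinder (the jet, default diameter 150 µm, axis
along Y) is centred in a slab of host medium (default 200 µm thick along
the beam axis Z, infinite in X and Y).  A Gaussian beam (default
85 × 85 µm FWHM) is launched at the cylinder from the side along +Z.
Defaults for the media: cylinder µa = 1 mm⁻¹, g = 0.9, n = 1.4, µs
configurable (0.1 / 9.8 / 53.8 mm⁻¹ represent a non-scattering jet, a
cellulose gel with crystals, and PTFE grease with crystals — total
scattering coefficients, i.e. forward plus backward); host µa = µs =
0.1 mm⁻¹, g = 0, n = 1 — small but non-zero, because a fluence estimator
needs interactions to be defined everywhere, and small enough over
200 µm that their effect is negligible.

Per photon packet: free paths are sampled as −ln(u)/µt in the current
medium; at each collision the fraction µa/µt of the weight is deposited
(discrete absorption weighting) and the packet deflects through a
Henyey–Greenstein angle with the medium's g (azimuth uniform); at the
cylinder surface the unpolarized Fresnel average decides specular
reflection vs Snell refraction, with total internal reflection beyond
the critical angle (this is the optical-fibre trapping mechanism that
distinguishes a jet from a flat cell); the slab outer faces are
index-matched and terminate photons.  Fluence is tallied by a
track-length estimator on a regular voxel grid (default 201 × 201 × 101
bins spanning 400 × 400 × 200 µm, edge-spanning convention), normalized
per voxel volume and per launched photon.  `axial_fluence_profile`
slices the cylinder into discs along its axis and averages fluence over
voxel centres inside the cross-section; an empty disc is reported as NaN
with a warning, never a silent zero.

### Variance reduction and termination

* Track-length estimation (rather than collision estimation) for voxel
  fluence: every traversed voxel scores on every flight, which is the
  low-variance choice at these optical thicknesses.  Absorption
  weighting governs only the weight carried, not the tally.
* Russian roulette below weight 1e−4 with survival probability 0.1;
  required for termination at the high single-scattering albedo
  (53.8/54.8 ≈ 0.98).  Roulette is unbiased; the weight it creates and
  destroys is booked separately so the per-batch identity
  absorbed + exited + roulette_loss − roulette_gain = launched closes to
  float round-off (asserted at 1e−9, and exactly without roulette).
* The RNG is seeded per run; identical configuration + seed gives a
  bit-identical tally.  Statistical, not bit-level, agreement with other
  transport codes is the goal.
* Polarization is ignored (unpolarized Fresnel average).

### Validation

The kernel is checked against limits with known answers: ballistic
transmission through the host slab (e^{−µt·d}), Beer–Lambert decay of
transversely integrated fluence across a negligible-scattering jet
(a narrow 10 µm test beam keeps incidence near normal, because at the
real 85 µm beam width the curved n = 1→1.4 surface acts as a lens and
focuses off-axis rays — a real effect, not an error, but one that
invalidates the 1-D decay comparison), Henyey–Greenstein sample moments
against quadrature of the phase-function density, Fresnel reflectance at
normal incidence, and conservation in a non-absorbing slab.  The
headline qualitative result is asserted as a property: across
µs ∈ {0.1, 9.8, 53.8} mm⁻¹ the fluence spilled beyond ±150 µm along the
jet grows monotonically (light contamination of nominally unpumped
sample) while the focal-disc fluence does not collapse.

Desk-scale photon counts are used throughout: a few ×10⁵ photons per
configuration in tests and analyses (seconds per run), against 10⁸ in a
production-scale run of the same physics.  All assertions on stochastic
outputs are made in units of batch-estimated Monte Carlo standard
errors, so they hold at any scale.

## 3. Displacement-scan analysis

### Procedure

The experiment displaces the pump focus by Δx along the jet relative to
a fixed probe and records probe spectra at positive (pumped, 10–50 ps)
and negative (unpumped background, −10…−1 ps) delays.  The analysis:

1. ΔA = −log₁₀(I_pumped/I_unpumped) per record; positive in the
   excited-state-absorption (ESA) band (435–445 nm for Nile red),
   negative in the ground-state-bleach band (615–625 nm).
2. For each (Δx, band), pool all positive-delay points across scans and
   wavelengths, and all negative-delay points separately.  Compress each
   pool with a median-filtered average: rank points by |value − pool
   median| (ties broken by record order), keep the closest
   ceil(0.5·n), return mean and sample standard deviation of the kept
   subset.  This rejects spectra recorded while the jet had wandered off
   the probe — the dominant outlier mode, which shows up as near-zero
   ΔA.
3. Signal = positive-pool mean − negative-pool mean; per-point error =
   √(σ₊² + σ₋²) (root-sum-square of the two kept-subset standard
   deviations, exactly).
4. Fit both band profiles globally with Gaussians sharing centre and
   FWHM, with per-band signed amplitude and a per-band constant offset,
   weighted by inverse variance (unweighted fallback when errors are
   degenerate).  The offset is included as a guard against imperfect
   background subtraction.
5. Compare the fitted FWHM with the width of the pump–probe overlap
   integral O(Δx) = ∫ I_pump(x−Δx) I_probe(x) dx / ∫ I_probe(x) dx —
   the no-scattering expectation, a Gaussian of width
   √(FWHM_pump² + FWHM_probe²) for Gaussian beams (asserted against the
   closed form to 1e−6).  Excess width means scattered pump light
   excited nominally unpumped jet regions.
6. Convert broadening to an intensity loss assuming area-conserving
   Gaussian redistribution: broadening = w_meas/w_overlap − 1 and
   peak-loss = 1 − w_overlap/w_meas.  For the measured 99 → 144 µm case
   this gives 45% broadening and a 31% ("~30%") peak loss.  The loss is
   an upper bound: if scattering lengthens the mean light path inside
   the jet (total internal reflection does exactly that), the integrated
   intensity along the jet rises and the true focal loss is smaller —
   the Monte Carlo stage shows the focal fluence barely drops.  A
   measured profile *narrower* than the overlap expectation (observed
   for clean jets, e.g. 83 vs 99 µm) reports zero loss with an
   explanatory note rather than a negative loss.

All three scans at a given Δx are pooled jointly rather than averaged
per scan first; widths are reported as FWHM in µm throughout.

### What the synthetic scans emulate — and what they do not

The generator produces records (scan, Δx, Δt, λ, ΔA) with: a two-band
Nile red spectral envelope (ESA Gaussian at 440 nm, bleach/stimulated-
emission Gaussian at 620 nm, both static), 2 nm spectral sampling over
the band neighbourhoods, delay pools at 10–50 ps and −10…−1 ps, three
scans per displacement, i.i.d. Gaussian noise (default σ = 8·10⁻⁴ on a
10⁻² peak ΔA, i.e. ~1 mOD noise on a ~10 mOD signal), and jet-miss
outliers that replace a whole (scan, Δx, Δt) spectrum with near-zero
values at a configurable probability (default studies use 20%).

The true excitation profile along the jet is a Gaussian core plus an
optional co-centred wider Gaussian carrying a "contamination tail"
fraction — the simplest unimodal shape consistent with a scattering-
broadened profile; an exponential-tail alternative was considered and
rejected as indistinguishable at realistic noise.  Because the pipeline
summarizes profiles by a single-Gaussian fit, the generator calibrates
its core width by root-finding so that the *fitted* FWHM of the
noiseless profile equals the requested target (e.g. 144 µm with a 0.3
tail fraction); with no tail the calibration is the exact quadrature
difference.  Ground truth is returned with every dataset, so pipeline
tests are parameter-recovery tests, never snapshots.

Not emulated: excited-state kinetics and the time-dependent redshift of
the stimulated-emission band, instrument response, chirp, probe
white-light fluctuations, and any correlation structure in the noise.
Passing recovery tests therefore demonstrates correctness of the
pooling/rejection/fit chain under the stated noise model, not
robustness to every instrumental artefact of a real beamline dataset.

## Parameter defaults that matter

| parameter | default | why |
|---|---|---|
| band windows | 435–445 / 615–625 nm | Nile red ESA and GSB integration ranges |
| delay pools | 10–50 ps, −10…−1 ps | signal plateau vs pre-zero background |
| rejection ratio | keep 50% closest to median | matches the jet-miss rejection procedure |
| pump / probe FWHM | 85 / 20 µm | measured beam sizes at the sample |
| jet diameter / slab | 150 / 200 µm | capillary inner diameter; host layer |
| cylinder µa, g, n | 1 mm⁻¹, 0.9, 1.4 | dyed medium absorption; large-particle forward scattering; lipid/water index |
| host µa = µs | 0.1 mm⁻¹ | negligible but non-zero for tallying |
| tally | 201×201×101 over 400×400×200 µm | ~2 µm voxels resolve the 85 µm beam |
| roulette | w < 1e−4, p = 0.1 | termination at albedo ≈ 0.98, unbiased |
| profiler pitch | 4.65 µm | beam-profiler camera pixel size |

## Known limitations

* The two-flux model assumes diffuse incidence and an infinite flat
  slab; it cannot represent the finite beam, the cylindrical jet, or
  collimated-to-diffuse conversion.  Those are exactly the gaps the
  Monte Carlo stage fills.
* The Monte Carlo is steady-state: path-length (temporal-smearing)
  histograms, polarization, and GPU-scale photon counts are not
  implemented.
* Reflectance-mode two-flux analysis and wavelength-dependent dispersion
  of the coefficients are out of scope; coefficients are fitted per
  wavelength.
* The displacement-scan amplitudes are not comparable across bands or
  against the overlap curve (the experimental normalization is a display
  choice), so only widths carry quantitative meaning.
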