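"""Seeded generators emulating every input class of the pipeline.

Three generators mirror the three experimental data streams:

* multi-path-length integrating-sphere transmittance tables (forward
  Kubelka-Munk model plus multiplicative noise),
* pump-probe displacement scans with the Nile red band structure (ESA
  ~440 nm positive, GSB ~620 nm negative), positive/negative delay pools,
  2 nm spectral sampling, Gaussian noise and jet-miss outlier spectra,
* 1-D beam-profiler traces on a 4.65 um pixel pitch.

Every generator takes a seed (or derives child streams from one) and
returns its ground truth alongside the records, so downstream tests are
parameter-recovery tests rather than snapshot tests.  The jet-miss
outliers replace a whole recorded spectrum by near-zero values -- the
failure mode the median-filtered average is designed to reject.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .km import KMCoefficients, TransmittanceDataset, km_transmittance
from .ta import BeamProfile

logger = logging.getLogger(__name__)

__all__ = [
    "SynthKMConfig",
    "SynthTAConfig",
    "SynthTAResult",
    "synth_transmittance",
    "synth_ta_scan",
    "synth_beam_profile",
    "expected_signal_shape",
    "calibrate_excitation_fwhm",
]

_S2F = 2.0 * math.sqrt(2.0 * math.log(2.0))  # sigma -> FWHM

BEAM_PROFILER_PITCH_UM = 4.65


@dataclass(frozen=True)
class SynthKMConfig:
    """Forward transmittance generator: truth coefficients, flat-cell path
    lengths (um), multiplicative noise sigma, replicate count, seed."""

    truth: KMCoefficients
    pathlengths_um: tuple[float, ...] = (22.0, 100.0, 200.0, 500.0)
    noise_sigma: float = 0.0
    replicates: int = 1
    seed: int = 0
    wavelength_nm: float = 515.0
    sample: str = "synthetic"

    def __post_init__(self) -> None:
        if len(set(self.pathlengths_um)) != len(self.pathlengths_um):
            raise ValueError("path lengths must be distinct")
        if any(d <= 0 for d in self.pathlengths_um):
            raise ValueError("path lengths must be positive")
        if self.noise_sigma < 0 or self.replicates < 1:
            raise ValueError("invalid noise sigma or replicate count")


def synth_transmittance(
    config: SynthKMConfig, replicate: int = 0
) -> TransmittanceDataset:
    """One noisy transmittance dataset: T_i = T_model(d_i) * (1 + eps_i),
    eps ~ Normal(0, sigma); values driven outside (0, 1] are clipped with
    a logged count.  Deterministic per (seed, replicate)."""
    if not 0 <= replicate < config.replicates:
        raise ValueError("replicate index out of range")
    rng = np.random.default_rng([config.seed, replicate])
    d_mm = np.asarray(config.pathlengths_um, dtype=float) / 1000.0
    T = np.array([km_transmittance(config.truth, d) for d in d_mm])
    if config.noise_sigma > 0:
        T = T * (1.0 + rng.normal(0.0, config.noise_sigma, size=T.size))
    n_clip = int(np.count_nonzero((T <= 0) | (T > 1)))
    if n_clip:
        logger.warning("clipped %d transmittances to (0, 1]", n_clip)
        T = np.clip(T, 1e-12, 1.0)
    return TransmittanceDataset(
        sample=config.sample,
        wavelength_nm=config.wavelength_nm,
        pathlengths_mm=d_mm,
        transmittance=T,
    )


@dataclass(frozen=True)
class SynthTAConfig:
    """Displacement-scan generator.

    The true excitation-intensity profile along the jet is a Gaussian of
    ``excitation_fwhm_um`` plus an optional co-centred contamination tail
    (a wider Gaussian mixture component carrying ``tail_fraction`` of the
    area, ``tail_scale`` times wider) -- the simplest shape consistent
    with a scattering-broadened but unimodal profile.  The expected dA is
    the probe-weighted overlap of that profile, modulated by the two-band
    Nile red spectral envelope.
    """

    excitation_fwhm_um: float = 85.0
    tail_fraction: float = 0.0
    tail_scale: float = 2.5
    probe_fwhm_um: float = 20.0
    dx_grid_um: tuple[float, ...] = tuple(np.arange(-240.0, 241.0, 30.0))
    dt_positive_ps: tuple[float, ...] = tuple(np.arange(10.0, 51.0, 5.0))
    dt_negative_ps: tuple[float, ...] = tuple(np.arange(-10.0, -0.5, 1.0))
    wavelength_grid_nm: tuple[float, ...] = tuple(
        np.concatenate([np.arange(430.0, 451.0, 2.0),
                        np.arange(610.0, 631.0, 2.0)])
    )
    esa_center_nm: float = 440.0
    esa_width_nm: float = 20.0
    esa_amplitude: float = 0.010
    gsb_center_nm: float = 620.0
    gsb_width_nm: float = 30.0
    gsb_amplitude: float = 0.010
    noise_sigma: float = 0.0008
    outlier_prob: float = 0.0
    n_scans: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.excitation_fwhm_um <= 0 or self.probe_fwhm_um <= 0:
            raise ValueError("beam FWHMs must be positive")
        if not 0.0 <= self.tail_fraction <= 1.0:
            raise ValueError("tail fraction must lie in [0, 1]")
        if self.tail_scale <= 1.0:
            raise ValueError("tail scale must exceed 1")
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise ValueError("outlier probability must lie in [0, 1]")
        if len(self.dx_grid_um) == 0 or len(self.wavelength_grid_nm) == 0:
            raise ValueError("grids must be non-empty")


@dataclass
class SynthTAResult:
    """Scan records plus the generator's ground truth."""

    records: pd.DataFrame
    true_excitation_fwhm_um: float
    true_profile_fwhm_um: float  # Gaussian-fit FWHM of the noiseless signal
    esa_amplitude: float
    gsb_amplitude: float
    config: SynthTAConfig


def _mixture_overlap(dx, core_fwhm, tail_fraction, tail_scale, probe_fwhm):
    """Probe-convolved excitation profile, normalized to peak 1 at dx=0.

    Both mixture components have unit area, so a Gaussian(FWHM w)
    convolved with the probe contributes a Gaussian of width
    sqrt(w^2 + w_probe^2) and peak ~ 1/width.
    """
    dx = np.asarray(dx, dtype=float)
    out = np.zeros_like(dx)
    peak = 0.0
    for frac, w in ((1.0 - tail_fraction, core_fwhm),
                    (tail_fraction, tail_scale * core_fwhm)):
        if frac == 0.0:
            continue
        w_conv = math.hypot(w, probe_fwhm)
        sigma = w_conv / _S2F
        amp = frac / (sigma * math.sqrt(2.0 * math.pi))
        out = out + amp * np.exp(-0.5 * (dx / sigma) ** 2)
        peak += amp
    return out / peak


def expected_signal_shape(config: SynthTAConfig, dx) -> np.ndarray:
    """Noiseless normalized signal shape vs displacement (peak 1)."""
    return _mixture_overlap(dx, config.excitation_fwhm_um,
                            config.tail_fraction, config.tail_scale,
                            config.probe_fwhm_um)


def _fitted_fwhm_of_shape(core_fwhm, tail_fraction, tail_scale, probe_fwhm):
    """FWHM a single-Gaussian least-squares fit assigns to the noiseless
    mixture shape (what the analysis pipeline would measure)."""
    x = np.linspace(-600.0, 600.0, 1201)
    y = _mixture_overlap(x, core_fwhm, tail_fraction, tail_scale, probe_fwhm)
    if tail_fraction == 0.0:
        return math.hypot(core_fwhm, probe_fwhm)

    def gauss(x, a, w, c):
        return a * np.exp(-4.0 * math.log(2.0) * x**2 / w**2) + c

    popt, _ = curve_fit(gauss, x, y, p0=(1.0, core_fwhm, 0.0))
    return abs(popt[1])


def calibrate_excitation_fwhm(
    target_profile_fwhm_um: float,
    probe_fwhm_um: float = 20.0,
    tail_fraction: float = 0.0,
    tail_scale: float = 2.5,
) -> float:
    """Core excitation FWHM such that the pipeline's single-Gaussian fit of
    the noiseless probe-convolved profile returns the requested width.

    With no tail this is the quadrature difference
    sqrt(target^2 - probe^2); with a contamination tail the width is found
    by deterministic root bracketing.
    """
    if target_profile_fwhm_um <= probe_fwhm_um:
        raise ValueError("target width must exceed the probe width")
    if tail_fraction == 0.0:
        return math.sqrt(target_profile_fwhm_um**2 - probe_fwhm_um**2)

    def objective(w):
        return (_fitted_fwhm_of_shape(w, tail_fraction, tail_scale,
                                      probe_fwhm_um)
                - target_profile_fwhm_um)

    lo = 1.0
    hi = target_profile_fwhm_um * 2.0
    return brentq(objective, lo, hi, xtol=1e-6)


def synth_ta_scan(config: SynthTAConfig) -> SynthTAResult:
    """Generate a full displacement scan with ground truth.

    Records carry columns scan, dx_um, dt_ps, wavelength_nm, dA.  Positive
    delays carry the band signal plus noise; negative delays noise only.
    With probability ``outlier_prob`` a whole (scan, dx, dt) spectrum is
    replaced by near-zero jet-miss values.
    """
    rng = np.random.default_rng(config.seed)
    lam = np.asarray(config.wavelength_grid_nm, dtype=float)
    ln2x4 = 4.0 * math.log(2.0)
    env = (config.esa_amplitude
           * np.exp(-ln2x4 * (lam - config.esa_center_nm) ** 2
                    / config.esa_width_nm**2)
           - config.gsb_amplitude
           * np.exp(-ln2x4 * (lam - config.gsb_center_nm) ** 2
                    / config.gsb_width_nm**2))
    dx_grid = np.asarray(config.dx_grid_um, dtype=float)
    shape = expected_signal_shape(config, dx_grid)

    delays = [(dt, True) for dt in config.dt_positive_ps] + \
             [(dt, False) for dt in config.dt_negative_ps]
    n_lam = lam.size
    frames = []
    for scan in range(config.n_scans):
        for i_dx, dx in enumerate(dx_grid):
            for dt, pumped in delays:
                if config.outlier_prob > 0 and rng.random() < config.outlier_prob:
                    dA = rng.normal(0.0, 0.1 * config.noise_sigma, n_lam)
                else:
                    signal = env * shape[i_dx] if pumped else 0.0
                    dA = signal + rng.normal(0.0, config.noise_sigma, n_lam)
                frames.append(pd.DataFrame({
                    "scan": scan,
                    "dx_um": dx,
                    "dt_ps": dt,
                    "wavelength_nm": lam,
                    "dA": dA,
                }))
    records = pd.concat(frames, ignore_index=True)
    true_profile_fwhm = _fitted_fwhm_of_shape(
        config.excitation_fwhm_um, config.tail_fraction, config.tail_scale,
        config.probe_fwhm_um)
    return SynthTAResult(
        records=records,
        true_excitation_fwhm_um=config.excitation_fwhm_um,
        true_profile_fwhm_um=true_profile_fwhm,
        esa_amplitude=config.esa_amplitude,
        gsb_amplitude=config.gsb_amplitude,
        config=config,
    )


def synth_beam_profile(
    fwhm_um: float,
    grid_um: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    pitch_um: float = BEAM_PROFILER_PITCH_UM,
) -> BeamProfile:
    """Gaussian beam-profiler trace on a regular pixel grid.

    The default grid mimics a beam-profiler camera with 4.65 um pixels
    spanning +-4 FWHM.  Fewer than 5 pixels per FWHM triggers a
    coarse-sampling warning (the FWHM estimate then carries a grid-scale
    error)."""
    if fwhm_um <= 0:
        raise ValueError("FWHM must be positive")
    if grid_um is None:
        half = 4.0 * fwhm_um
        n = int(round(2 * half / pitch_um)) + 1
        grid_um = (np.arange(n) - (n - 1) / 2) * pitch_um
    grid_um = np.asarray(grid_um, dtype=float)
    step = float(np.median(np.diff(grid_um)))
    if fwhm_um / step < 5.0:
        warnings.warn(
            f"coarse sampling: only {fwhm_um / step:.1f} points per FWHM")
    rng = np.random.default_rng(seed)
    y = np.exp(-4.0 * math.log(2.0) * grid_um**2 / fwhm_um**2)
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, y.size)
    return BeamProfile(x_um=grid_um, intensity=np.clip(y, 0.0, None))
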