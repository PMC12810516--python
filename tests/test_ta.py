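"""Displacement-scan analysis: dA, robust pooling, overlap, global fit."""

import math

import numpy as np
import pandas as pd
import pytest

from jetlight import (
    BeamProfile,
    SynthTAConfig,
    build_displacement_profile,
    calibrate_excitation_fwhm,
    compute_delta_A,
    estimate_fwhm,
    global_gaussian_fit,
    intensity_loss_estimate,
    median_filtered_average,
    overlap_integral,
    synth_ta_scan,
)
from .oracles import gaussian_overlap_curve, gaussian_overlap_fwhm


class TestDeltaA:
    @pytest.mark.parametrize(
        "ip, iu, expected",
        [
            (1.0, 1.0, 0.0),
            (0.5, 1.0, math.log10(2.0)),    # more absorption when pumped (ESA)
            (2.0, 1.0, -math.log10(2.0)),   # bleach lets more probe through
        ],
    )
    def test_definition(self, ip, iu, expected):
        assert compute_delta_A(ip, iu) == pytest.approx(expected, abs=1e-12)

    def test_scalar_nonpositive_raises(self):
        with pytest.raises(ValueError):
            compute_delta_A(0.0, 1.0)

    def test_array_rejects_bad_records_as_nan(self, caplog):
        out = compute_delta_A(np.array([1.0, 0.0, 2.0]),
                              np.array([1.0, 1.0, -1.0]))
        assert np.isnan(out[1]) and np.isnan(out[2])
        assert out[0] == 0.0


class TestMedianFilteredAverage:
    def test_constant_pool(self):
        assert median_filtered_average([5, 5, 5, 5]) == (5.0, 0.0, 2)

    def test_hand_enumerated_ranking(self):
        """Pool [1,2,3,4,100]: median 3, distances [2,1,0,1,97]; the
        ceil(2.5)=3 closest are {3, 2, 4} (the 2/4 tie ranks before the
        outlier), so the robust mean is 3."""
        mean, std, kept = median_filtered_average([1, 2, 3, 4, 100])
        assert kept == 3
        assert mean == pytest.approx(3.0)
        assert std == pytest.approx(1.0)  # sample std of {2, 3, 4}

    def test_kept_count_is_ceil(self):
        for n in (1, 2, 3, 7, 10):
            _, _, kept = median_filtered_average(np.arange(n) * 0.1 + 1)
            assert kept == math.ceil(0.5 * n)

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            median_filtered_average([])

    def test_single_point_warns(self):
        with pytest.warns(UserWarning):
            mean, std, kept = median_filtered_average([0.7])
        assert (mean, std, kept) == (0.7, 0.0, 1)

    def test_rejects_jet_miss_dropouts(self, rng):
        """10^4 signal points at 0.1 plus 30% near-zero dropouts: the
        filtered mean lands within one kept-subset std of the true level,
        and far closer than the naive mean (the filter's purpose)."""
        signal = rng.normal(0.1, 0.01, 10_000)
        dropouts = np.zeros(3_000)
        pool = rng.permutation(np.concatenate([signal, dropouts]))
        mean, std, _ = median_filtered_average(pool)
        assert abs(mean - 0.1) < std
        assert abs(mean - 0.1) < abs(pool.mean() - 0.1) / 3


def _gauss_beam(fwhm, span=400.0, n=2001):
    x = np.linspace(-span, span, n)
    return BeamProfile(x_um=x, intensity=np.exp(
        -4 * math.log(2) * x**2 / fwhm**2))


class TestOverlapIntegral:
    def test_autocorrelation_width(self):
        o = overlap_integral(_gauss_beam(60.0), _gauss_beam(60.0),
                             np.linspace(-300, 300, 1201))
        assert o.fwhm_um == pytest.approx(60.0 * math.sqrt(2.0), rel=1e-3)

    def test_pump85_probe20_quadrature_sum(self):
        o = overlap_integral(_gauss_beam(85.0), _gauss_beam(20.0),
                             np.linspace(-300, 300, 1201))
        assert o.fwhm_um == pytest.approx(gaussian_overlap_fwhm(85, 20),
                                          rel=1e-3)

    def test_matches_closed_form_curve(self):
        """Numerical cross-correlation vs the analytic Gaussian overlap,
        pointwise to 1e-6 relative on a fine grid."""
        dx = np.linspace(-250, 250, 501)
        o = overlap_integral(_gauss_beam(85.0, 600, 12001),
                             _gauss_beam(20.0, 600, 12001), dx)
        expected = gaussian_overlap_curve(dx, 85.0, 20.0)
        np.testing.assert_allclose(o.value, expected, rtol=2e-6, atol=1e-12)

    def test_narrow_probe_sifts_pump_profile(self):
        pump = _gauss_beam(85.0)
        probe = _gauss_beam(0.5)
        dx = np.linspace(-200, 200, 801)
        o = overlap_integral(pump, probe, dx)
        np.testing.assert_allclose(
            o.value, np.exp(-4 * math.log(2) * dx**2 / 85.0**2), atol=2e-4)

    def test_disjoint_supports_warn(self):
        pump = BeamProfile(x_um=np.linspace(0, 10, 11),
                           intensity=np.ones(11))
        probe = BeamProfile(x_um=np.linspace(1000, 1010, 11),
                            intensity=np.ones(11))
        with pytest.warns(UserWarning, match="overlap"):
            o = overlap_integral(pump, probe, np.array([0.0, 5.0]))
        assert np.all(o.value == 0.0)


def _noiseless_profile(fwhm, seed=0, **kw):
    cfg = SynthTAConfig(
        excitation_fwhm_um=calibrate_excitation_fwhm(fwhm, 20.0),
        probe_fwhm_um=20.0, noise_sigma=0.0, outlier_prob=0.0, seed=seed,
        **kw)
    return build_displacement_profile(synth_ta_scan(cfg).records)


class TestBuildDisplacementProfile:
    def test_null_scan_consistent_with_zero(self):
        cfg = SynthTAConfig(esa_amplitude=0.0, gsb_amplitude=0.0,
                            noise_sigma=0.001, seed=42)
        prof = build_displacement_profile(synth_ta_scan(cfg).records)
        t = prof.table
        # kept-subset std >> standard error of the robust mean; 3x the
        # propagated per-point error is a generous zero-consistency bound
        assert np.all(np.abs(t["signal"]) < 3.0 * t["err"])

    def test_noiseless_profile_proportional_to_overlap(self):
        from jetlight.synthetic import expected_signal_shape
        cfg = SynthTAConfig(noise_sigma=0.0, outlier_prob=0.0, seed=0)
        res = synth_ta_scan(cfg)
        prof = build_displacement_profile(res.records)
        dx, sig, _ = prof.band_arrays("ESA")
        shape = expected_signal_shape(cfg, dx)
        ratio = sig / shape
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_error_is_root_sum_square_of_pool_stds(self):
        """The reported per-point error equals hypot of the two kept-pool
        standard deviations exactly."""
        lam = 440.0
        rows = []
        pos_vals = [0.010, 0.011, 0.012, 0.013]
        neg_vals = [0.000, 0.001, -0.001, 0.0005]
        for dx in (0.0, 30.0, 60.0):
            for v in pos_vals:
                rows.append((0, dx, 20.0, lam, v))
            for v in neg_vals:
                rows.append((0, dx, -5.0, lam, v))
        records = pd.DataFrame(
            rows, columns=["scan", "dx_um", "dt_ps", "wavelength_nm", "dA"])
        prof = build_displacement_profile(records)
        _, s_pos, k = median_filtered_average(pos_vals)
        _, s_neg, _ = median_filtered_average(neg_vals)
        t = prof.table
        np.testing.assert_allclose(t["err"], math.hypot(s_pos, s_neg))
        assert set(t["n_kept_pos"]) == {k}

    def test_outlier_contaminated_scan_matches_clean_one(self):
        base = dict(excitation_fwhm_um=calibrate_excitation_fwhm(99.0, 20.0),
                    noise_sigma=0.0008)
        clean = synth_ta_scan(SynthTAConfig(seed=5, outlier_prob=0.0, **base))
        dirty = synth_ta_scan(SynthTAConfig(seed=5, outlier_prob=0.2, **base))
        f_clean = global_gaussian_fit(build_displacement_profile(clean.records))
        f_dirty = global_gaussian_fit(build_displacement_profile(dirty.records))
        assert f_dirty.fwhm_um == pytest.approx(f_clean.fwhm_um, rel=0.05)

    def test_intensity_pair_input(self):
        records = pd.DataFrame({
            "scan": 0,
            "dx_um": np.repeat([0.0, 30.0, 60.0, 90.0], 4),
            "dt_ps": np.tile([20.0, 20.0, -5.0, -5.0], 4),
            "wavelength_nm": 440.0,
            "i_pumped": 0.95,
            "i_unpumped": 1.0,
        })
        prof = build_displacement_profile(records)
        assert np.allclose(prof.table["signal"], 0.0, atol=1e-12)

    def test_too_few_displacements_rejected(self):
        records = pd.DataFrame({
            "scan": 0, "dx_um": [0.0] * 4 + [30.0] * 4,
            "dt_ps": [20.0, -5.0] * 4, "wavelength_nm": 440.0, "dA": 0.01})
        with pytest.raises(ValueError, match="displacement"):
            build_displacement_profile(records)


class TestGlobalGaussianFit:
    def test_noiseless_roundtrip_fwhm(self):
        fit = global_gaussian_fit(_noiseless_profile(99.0))
        assert fit.converged
        assert fit.fwhm_um == pytest.approx(99.0, abs=1e-6)
        assert fit.center_um == pytest.approx(0.0, abs=1e-6)

    def test_signs_follow_band_structure(self):
        fit = global_gaussian_fit(_noiseless_profile(99.0))
        assert fit.amplitude["ESA"] > 0 > fit.amplitude["GSB"]

    def test_shared_width_is_compromise_of_band_widths(self):
        """Bands generated with different true widths (90 and 110 um):
        the shared-FWHM fit lands between them."""
        lam = np.array([440.0, 620.0])
        dx = np.arange(-200.0, 201.0, 25.0)
        rows = []
        for d in dx:
            for wl, w, sign in ((440.0, 90.0, 1), (620.0, 110.0, -1)):
                val = sign * 0.01 * math.exp(-4 * math.log(2) * d**2 / w**2)
                for dt in (15.0, 25.0, 35.0):
                    rows.append((0, d, dt, wl, val))
                for dt in (-8.0, -4.0, -2.0):
                    rows.append((0, d, dt, wl, 0.0))
        records = pd.DataFrame(
            rows, columns=["scan", "dx_um", "dt_ps", "wavelength_nm", "dA"])
        fit = global_gaussian_fit(build_displacement_profile(records))
        assert 90.0 < fit.fwhm_um < 110.0

    def test_flat_cell_regime_envelope(self, rng):
        """Flat-cell conditions (pump 102 um, probe 20 um, modest noise)
        give fitted widths inside the plausible 93-114 um window."""
        w = calibrate_excitation_fwhm(gaussian_overlap_fwhm(102.0, 20.0), 20.0)
        for seed in range(3):
            cfg = SynthTAConfig(excitation_fwhm_um=w, noise_sigma=0.0008,
                                outlier_prob=0.1, seed=700 + seed)
            fit = global_gaussian_fit(
                build_displacement_profile(synth_ta_scan(cfg).records))
            assert 93.0 <= fit.fwhm_um <= 114.0

    def test_flat_profile_amplitude_consistent_with_zero(self):
        cfg = SynthTAConfig(esa_amplitude=0.0, gsb_amplitude=0.0,
                            noise_sigma=0.0005, seed=9)
        fit = global_gaussian_fit(
            build_displacement_profile(synth_ta_scan(cfg).records))
        for amp in fit.amplitude.values():
            assert abs(amp) < 0.001


class TestIntensityLoss:
    def test_measured_broadening_arithmetic(self):
        """99 -> 144 um redistribution: 45% broadening, ~30% peak loss."""
        est = intensity_loss_estimate(99.0, 144.0)
        assert est.broadening == pytest.approx(45.0 / 99.0, abs=1e-12)
        assert est.peak_loss == pytest.approx(1.0 - 99.0 / 144.0, abs=1e-12)
        assert round(100 * est.broadening) == 45
        assert est.peak_loss == pytest.approx(0.31, abs=0.005)

    def test_no_broadening_no_loss(self):
        est = intensity_loss_estimate(99.0, 99.0)
        assert est.broadening == 0.0 and est.peak_loss == 0.0

    def test_narrower_than_overlap_reports_zero_with_note(self):
        est = intensity_loss_estimate(99.0, 83.0)
        assert est.peak_loss == 0.0 and est.broadening == 0.0
        assert "narrower" in est.note

    def test_invalid_widths(self):
        with pytest.raises(ValueError):
            intensity_loss_estimate(0.0, 100.0)


class TestFwhmEstimator:
    def test_exact_on_fine_gaussian(self):
        x = np.linspace(-300, 300, 6001)
        y = np.exp(-4 * math.log(2) * x**2 / 123.0**2)
        assert estimate_fwhm(x, y) == pytest.approx(123.0, abs=0.05)

    def test_unbracketed_half_maximum_raises(self):
        x = np.linspace(0, 10, 21)
        with pytest.raises(ValueError):
            estimate_fwhm(x, x.copy())  # peak at the edge: no right crossing
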