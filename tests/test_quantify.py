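import math

import numpy as np
import pytest

from etherdnp.quantify import (BaselineSpec, PpmWindow, QuantificationError,
                               WINDOW_C2_FREE, WINDOW_C2_SUB, c2_fraction,
                               default_anchor_regions, estimate_uncertainty,
                               fit_baseline, integrate, phase_correct,
                               quantify_pair, subtract_control,
                               transfer_relative_uncertainty)
from etherdnp.spectra import AcquisitionMeta, Spectrum1D
from etherdnp.synthetic import (PeakSpec, SyntheticSceneSpec, lineshape,
                                make_spectrum, make_transfer_pair)


def flat_spectrum(n=2048, hi=230.0, lo=-30.0, value=0.0):
    axis = np.linspace(hi, lo, n)
    return Spectrum1D(axis, np.full(n, value), meta=AcquisitionMeta())


class TestPhaseCorrect:
    def test_zero_phase_is_identity(self):
        spec = flat_spectrum(value=1.5)
        out = phase_correct(spec, 0.0, 0.0)
        np.testing.assert_array_equal(out.intensity, spec.intensity)

    def test_dispersive_lorentzian_rephased_to_absorption(self):
        axis = np.linspace(150.0, 50.0, 4096)
        gamma = 1.0
        delta = axis - 100.0
        absorption = gamma / (delta ** 2 + gamma ** 2)
        dispersion = delta / (delta ** 2 + gamma ** 2)
        # a -90 degree phase error turns absorption into dispersion
        s = (absorption + 1j * dispersion) * np.exp(-1j * math.pi / 2)
        spec = Spectrum1D(axis, s.real, meta=AcquisitionMeta(),
                          intensity_imag=s.imag)
        out = phase_correct(spec, 90.0)
        assert abs(axis[np.argmax(out.intensity)] - 100.0) < 0.1
        np.testing.assert_allclose(out.intensity, absorption, atol=1e-10)

    def test_phase_inverse(self):
        rng = np.random.default_rng(0)
        axis = np.linspace(150.0, 50.0, 512)
        spec = Spectrum1D(axis, rng.normal(size=512), meta=AcquisitionMeta(),
                          intensity_imag=rng.normal(size=512))
        out = phase_correct(phase_correct(spec, 37.0, 11.0), -37.0, -11.0)
        np.testing.assert_allclose(out.intensity, spec.intensity, atol=1e-10)

    def test_first_order_on_real_only_rejected(self):
        with pytest.raises(ValueError, match="real-only"):
            phase_correct(flat_spectrum(), 0.0, 45.0)


class TestBaseline:
    def test_exact_polynomial_removed_everywhere(self):
        spec = flat_spectrum(n=4096)
        xs = (spec.ppm_axis - 100.0) / 130.0
        drift = 3.0 + 2.0 * xs - 1.5 * xs ** 3 + 0.7 * xs ** 5
        spec = spec.copy(intensity=drift * 1e4)
        _, corrected = fit_baseline(spec, BaselineSpec(order=5))
        assert np.max(np.abs(corrected.intensity)) < 1e-8 * np.max(np.abs(spec.intensity))

    def test_flat_zero_gives_zero_baseline(self):
        baseline, corrected = fit_baseline(flat_spectrum(), BaselineSpec())
        np.testing.assert_allclose(baseline, 0.0, atol=1e-12)
        np.testing.assert_allclose(corrected.intensity, 0.0, atol=1e-12)

    def test_peaks_plus_known_drift(self):
        sigma_noise = 0.01
        scene = SyntheticSceneSpec(
            peaks=[PeakSpec(84.0, 1.0, shape="gaussian"),
                   PeakSpec(75.0, 1.0, shape="gaussian")],
            baseline_poly=(0.5, 0.4, -0.3, 0.2), noise_sigma=sigma_noise, seed=9)
        spec = make_spectrum(scene)
        _, corrected = fit_baseline(spec)
        # anchor-region residuals after correction are at the noise level
        for w in default_anchor_regions(spec):
            sel = (spec.ppm_axis >= w.lo) & (spec.ppm_axis <= w.hi)
            assert np.std(corrected.intensity[sel]) < 1.5 * sigma_noise

    def test_idempotence(self):
        scene = SyntheticSceneSpec(
            peaks=[PeakSpec(84.0, 1.0, shape="gaussian")],
            baseline_poly=(0.5, 0.4, -0.3), noise_sigma=0.0, seed=0)
        spec = make_spectrum(scene)
        _, once = fit_baseline(spec)
        _, twice = fit_baseline(once)
        assert (np.max(np.abs(twice.intensity - once.intensity))
                < 1e-8 * np.max(np.abs(once.intensity)))

    def test_insufficient_anchor_points_rejected(self):
        spec = flat_spectrum(n=2048)
        tiny = BaselineSpec(order=5, anchor_regions=[PpmWindow(100.2, 100.0)])
        with pytest.raises(QuantificationError, match="anchor"):
            fit_baseline(spec, tiny)

    def test_overlapping_anchor_regions_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            BaselineSpec(anchor_regions=[PpmWindow(100.0, 50.0),
                                         PpmWindow(60.0, 20.0)])


class TestSubtractControl:
    def test_identical_spectra_cancel(self):
        spec = make_spectrum(SyntheticSceneSpec(
            peaks=[PeakSpec(84.0, 1.0)], noise_sigma=0.0, seed=0))
        diff = subtract_control(spec, spec)
        np.testing.assert_allclose(diff.intensity, 0.0, atol=1e-14)

    def test_zero_control_leaves_transfer(self):
        spec = make_spectrum(SyntheticSceneSpec(
            peaks=[PeakSpec(84.0, 1.0)], noise_sigma=0.0, seed=0))
        zero = spec.copy(intensity=np.zeros(spec.n_points))
        diff = subtract_control(spec, zero)
        np.testing.assert_array_equal(diff.intensity, spec.intensity)

    def test_per_scan_normalization(self):
        axis = np.linspace(150.0, 50.0, 256)
        base = np.exp(-((axis - 84.0) ** 2))
        transfer = Spectrum1D(axis, 4 * base, meta=AcquisitionMeta(n_scans=4))
        control = Spectrum1D(axis, 16 * base, meta=AcquisitionMeta(n_scans=16))
        diff = subtract_control(transfer, control)
        np.testing.assert_allclose(diff.intensity, 0.0, atol=1e-12)

    def test_artifact_removed_from_difference(self):
        transfer, control, _ = make_transfer_pair(0.5, snr=1e9, artifact_amp=0.2,
                                                  seed=0)
        diff = subtract_control(transfer, control)
        artifact_only = lineshape(diff.ppm_axis,
                                  PeakSpec(80.0, 0.2, fwhm=3.0, shape="pseudo_voigt"))
        window = (diff.ppm_axis <= 82.0) & (diff.ppm_axis >= 78.0)
        c2 = (lineshape(diff.ppm_axis, PeakSpec(84.0, 0.5, shape="gaussian"))
              + lineshape(diff.ppm_axis, PeakSpec(75.0, 0.5, shape="gaussian")))
        residual_artifact = np.abs(diff.intensity - c2)[window].max()
        assert residual_artifact < 0.05 * artifact_only[window].max()

    def test_incompatible_axes_rejected(self):
        a = flat_spectrum(hi=230.0, lo=-30.0)
        b = flat_spectrum(hi=100.0, lo=50.0)
        with pytest.raises(QuantificationError, match="cover"):
            subtract_control(a, b)


class TestIntegrate:
    def test_zero_spectrum(self):
        assert integrate(flat_spectrum(), (90.1, 80.4)) == 0.0

    def test_unit_rectangle_equals_width(self):
        axis = np.linspace(100.0, 50.0, 5001)  # 0.01-ppm grid
        inten = np.where((axis >= 70.0) & (axis <= 80.0), 1.0, 0.0)
        spec = Spectrum1D(axis, inten, meta=AcquisitionMeta())
        assert integrate(spec, (80.0, 70.0)) == pytest.approx(10.0, rel=1e-3)

    def test_lorentzian_known_area(self):
        axis = np.linspace(230.0, -30.0, 16384)
        area, fwhm, half_window = 2.5, 1.0, 40.0
        spec = Spectrum1D(axis, lineshape(axis, PeakSpec(84.0, area, fwhm=fwhm)),
                          meta=AcquisitionMeta())
        # closed-form Lorentzian mass inside a symmetric window
        captured = area * (2.0 / math.pi) * math.atan(2.0 * half_window / fwhm)
        assert integrate(spec, (84.0 + half_window, 84.0 - half_window)) == \
            pytest.approx(captured, rel=1e-3)

    def test_window_additivity(self):
        spec = make_spectrum(SyntheticSceneSpec(
            peaks=[PeakSpec(84.0, 1.0), PeakSpec(75.0, 0.7)],
            noise_sigma=0.02, seed=3))
        total = integrate(spec, (90.1, 71.9))
        parts = integrate(spec, WINDOW_C2_SUB) + integrate(spec, WINDOW_C2_FREE)
        assert parts == pytest.approx(total, abs=1e-10 * max(1.0, abs(total)))

    def test_window_outside_axis_rejected(self):
        with pytest.raises(ValueError):
            integrate(flat_spectrum(hi=100.0, lo=50.0), (120.0, 80.0))


class TestC2Fraction:
    def _spec_with_peaks(self, area_sub, area_free, noise=0.0, seed=0):
        return make_spectrum(SyntheticSceneSpec(
            peaks=[PeakSpec(84.0, area_sub, shape="gaussian"),
                   PeakSpec(75.0, area_free, shape="gaussian")],
            noise_sigma=noise, seed=seed))

    def test_all_signal_substituted(self):
        res = c2_fraction(self._spec_with_peaks(1.0, 0.0))
        assert res.pct_substituted == pytest.approx(100.0, abs=0.1)

    def test_equal_peaks_give_fifty(self):
        res = c2_fraction(self._spec_with_peaks(0.7, 0.7))
        assert res.pct_substituted == pytest.approx(50.0, abs=0.5)

    def test_no_signal_rejected(self):
        with pytest.raises(QuantificationError, match="no signal"):
            c2_fraction(flat_spectrum())

    def test_provenance_non_empty(self):
        res = c2_fraction(self._spec_with_peaks(1.0, 1.0))
        assert res.provenance
        assert "integrated" in res.provenance[-1]

    def test_summary_clamps_but_storage_does_not(self):
        spec = self._spec_with_peaks(1.0, 0.0)
        # inject a slightly negative free window
        spec = spec.copy(intensity=spec.intensity
                         - 0.001 * (np.abs(spec.ppm_axis - 75.0) < 1.0))
        with pytest.warns(UserWarning, match="negative"):
            res = c2_fraction(spec)
        assert res.pct_substituted > 100.0
        assert "100.0" in res.summary()


class TestPipeline:
    def test_scale_invariance(self):
        transfer, control, _ = make_transfer_pair(0.5, snr=20, artifact_amp=0.1,
                                                  seed=4, drift_amp=0.3)
        r1 = quantify_pair(transfer, control)
        c = 7.3e5
        r2 = quantify_pair(transfer.copy(intensity=c * transfer.intensity),
                           control.copy(intensity=c * control.intensity))
        assert r2.pct_substituted == pytest.approx(r1.pct_substituted, abs=1e-10)

    @pytest.mark.parametrize("p", [0.3, 0.5, 0.7])
    def test_end_to_end_recovery_snr20(self, p):
        # artifact at 20% of the C2 area and polynomial drift present
        errs = []
        for seed in (1, 2, 3):
            transfer, control, truth = make_transfer_pair(
                p, snr=20, artifact_amp=0.2, seed=seed, drift_amp=0.3)
            res = quantify_pair(transfer, control)
            errs.append(res.pct_substituted - truth["pct_substituted"])
        assert np.all(np.abs(errs) <= 3.0)

    def test_noiseless_perfect_pipeline(self):
        transfer, control, _ = make_transfer_pair(1.0, snr=1e9, artifact_amp=0.0,
                                                  seed=0)
        res = quantify_pair(transfer, control)
        assert res.pct_substituted == pytest.approx(100.0, abs=0.1)


class TestUncertainty:
    def test_identical_replicates_give_zero(self):
        spec = make_spectrum(SyntheticSceneSpec(
            peaks=[PeakSpec(84.0, 1.0, shape="gaussian"),
                   PeakSpec(75.0, 1.0, shape="gaussian")], noise_sigma=0.0, seed=0))
        res = c2_fraction(spec)
        assert estimate_uncertainty([res, res, res]) == 0.0

    def test_replicate_sd_needs_two(self):
        with pytest.raises(ValueError):
            estimate_uncertainty([], mode="replicate_sd")

    def test_noise_propagation_seeded_and_reproducible(self):
        transfer, control, _ = make_transfer_pair(0.5, snr=10, artifact_amp=0.1,
                                                  seed=6)
        kwargs = dict(mode="noise_propagation", transfer=transfer,
                      control=control, noise_sigma=0.005, n_draws=12, seed=42)
        u1 = estimate_uncertainty(**kwargs)
        u2 = estimate_uncertainty(**kwargs)
        assert u1 == u2
        assert 0.0 < u1 < 20.0

    def test_anchor_perturbation_mode(self):
        transfer, control, _ = make_transfer_pair(0.5, snr=20, artifact_amp=0.1,
                                                  seed=7, drift_amp=0.5)
        u = estimate_uncertainty(mode="anchor_perturbation", transfer=transfer,
                                 control=control, n_draws=8, seed=1)
        assert 0.0 <= u < 20.0

    def test_relative_uncertainty_transfer(self):
        # a 53 +/- 12 reference maps a 59 result to +/- 13
        assert transfer_relative_uncertainty(53.0, 12.0, 59.0) == pytest.approx(
            13.0, abs=0.5)
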