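"""Optical-constant extraction: FFT, phase, n, alpha, validity band."""

import numpy as np
import pytest

import teraspec as ts
from teraspec.forward import C_MM_PS

from conftest import in_instrument_band


def _tone(freq_thz, n=2048, dt=0.02):
    t = np.arange(n) * dt
    return ts.TimeTrace(t=t, e=np.cos(2 * np.pi * freq_thz * t))


class TestFftSpectrum:
    def test_single_tone_peaks_at_its_frequency(self):
        spec = ts.fft_spectrum(_tone(1.0), pad_factor=1)
        assert spec.nu[np.argmax(spec.magnitude)] == pytest.approx(1.0, abs=0.03)

    def test_zero_trace_zero_magnitude(self):
        tr = ts.TimeTrace(t=np.arange(128) * 0.02, e=np.zeros(128))
        assert np.all(ts.fft_spectrum(tr).magnitude == 0)

    def test_matches_naive_dft_sum(self, clean_pulse):
        """FFT equals the direct O(N^2) discrete Fourier sum."""
        spec = ts.fft_spectrum(clean_pulse, pad_factor=1)
        # probe inside the signal band; a relative comparison is
        # meaningless where the spectrum underflows
        probe = slice(10, 105, 7)
        naive = np.array([
            np.sum(clean_pulse.e * np.exp(-2j * np.pi * f * clean_pulse.t))
            for f in spec.nu[probe]
        ]) * clean_pulse.dt_ps
        np.testing.assert_allclose(np.abs(naive), spec.magnitude[probe], rtol=1e-10)

    def test_unwrapped_phase_steps_below_pi(self, clean_pulse):
        spec = ts.fft_spectrum(clean_pulse)
        assert np.all(np.abs(np.diff(spec.phase_unwrapped)) < np.pi)

    def test_short_trace_rejected(self):
        with pytest.raises(ts.ValidationError):
            ts.TimeTrace(t=np.arange(32) * 0.02, e=np.zeros(32))

    def test_bad_pad_factor_rejected(self, clean_pulse):
        with pytest.raises(ts.ValidationError):
            ts.fft_spectrum(clean_pulse, pad_factor=3)


class TestPhaseDifference:
    def test_self_reference_zero_phase(self, clean_pulse):
        spec = ts.fft_spectrum(clean_pulse)
        np.testing.assert_allclose(ts.phase_difference(spec, spec), 0.0, atol=1e-12)

    def test_pure_delay_linear_phase(self):
        """Delaying the pulse by 1.554 ps gives phi = 2 pi nu dt, positive."""
        dtau = 1.554
        a = ts.generate_reference_pulse(snr=float("inf"), seed=None)
        b = ts.generate_reference_pulse(t0_ps=5.0 + dtau, snr=float("inf"), seed=None)
        sa, sb = ts.fft_spectrum(a), ts.fft_spectrum(b)
        phi = ts.phase_difference(sb, sa)
        m = (sa.nu >= 0.2) & (sa.nu <= 0.4)
        np.testing.assert_allclose(phi[m], 2 * np.pi * sa.nu[m] * dtau, atol=1e-6)

    def test_grid_mismatch_rejected(self, clean_pulse):
        s1 = ts.fft_spectrum(clean_pulse, pad_factor=2)
        s2 = ts.fft_spectrum(clean_pulse, pad_factor=4)
        with pytest.raises(ts.IncompatibleSpectraError):
            ts.phase_difference(s1, s2)


class TestRefractiveIndex:
    def test_zero_phase_gives_vacuum(self):
        nu = np.linspace(0.2, 2.6, 100)
        np.testing.assert_allclose(ts.refractive_index(np.zeros(100), nu, 1.11), 1.0)

    def test_algebraic_inversion_constant_index(self):
        nu = np.linspace(0.2, 2.6, 100)
        d = 1.11
        phi = 2 * np.pi * nu * d * (1.42 - 1.0) / C_MM_PS
        np.testing.assert_allclose(ts.refractive_index(phi, nu, d), 1.42, rtol=1e-12)

    def test_invalid_thickness_rejected(self):
        with pytest.raises(ts.ValidationError):
            ts.refractive_index(np.zeros(10), np.linspace(1, 2, 10), 0.0)


class TestAbsorptionCoefficient:
    def test_fresnel_only_loss_gives_zero(self):
        n = np.full(50, 1.5)
        rho = 4 * n / (n + 1) ** 2
        alpha = ts.absorption_coefficient(rho, np.ones(50), n, 1.0)
        np.testing.assert_allclose(alpha, 0.0, atol=1e-12)

    def test_forward_inverse_consistency(self):
        """rho built for alpha = 10 cm^-1 through 1 mm recovers exactly 10."""
        n = np.array([1.5])
        rho = (4 * 1.5 / 2.5**2) * np.exp(-0.5 * 10.0 * 0.1)
        alpha = ts.absorption_coefficient(np.array([rho]), np.ones(1), n, 1.0)
        assert alpha[0] == pytest.approx(10.0, abs=1e-9)

    def test_halving_ratio_adds_log_two(self):
        n = np.full(5, 1.4)
        a1 = ts.absorption_coefficient(np.full(5, 0.5), np.ones(5), n, 2.0)
        a2 = ts.absorption_coefficient(np.full(5, 0.25), np.ones(5), n, 2.0)
        np.testing.assert_allclose(a2 - a1, (2.0 / 0.2) * np.log(2.0), rtol=1e-12)

    def test_common_rescaling_invariance(self, clean_pulse):
        """alpha is unchanged when both traces are scaled by the same factor."""
        model, geom = ts.preset("erythritol_solid")
        sam = ts.transmit(clean_pulse, model, geom)
        oc1 = ts.extract_optical_constants(sam, clean_pulse, geom.d_mm)
        scaled_ref = ts.TimeTrace(t=clean_pulse.t, e=clean_pulse.e * 7.3)
        scaled_sam = ts.TimeTrace(t=sam.t, e=sam.e * 7.3)
        oc2 = ts.extract_optical_constants(scaled_sam, scaled_ref, geom.d_mm)
        m = in_instrument_band(oc1)
        np.testing.assert_allclose(oc2.alpha_cm[m], oc1.alpha_cm[m], atol=1e-9)


class TestValidBand:
    def test_noise_free_pulse_covers_instrument_band(self, clean_pulse):
        band = ts.valid_band(ts.fft_spectrum(clean_pulse))
        assert band[0] <= 0.3 and band[1] >= 2.6

    def test_all_noise_trace_has_no_band(self):
        rng = np.random.default_rng(0)
        tr = ts.TimeTrace(t=np.arange(2048) * 0.02, e=rng.normal(size=2048))
        with pytest.raises(ts.EmptyBandError):
            ts.valid_band(ts.fft_spectrum(tr), floor_db=30.0)

    def test_raising_floor_never_widens_band(self, clean_pulse):
        spec = ts.fft_spectrum(ts.add_noise(clean_pulse, 1000, 3))
        widths = []
        for db in (20, 30, 40, 50):
            lo, hi = ts.valid_band(spec, floor_db=db)
            widths.append(hi - lo)
        assert all(w2 <= w1 for w1, w2 in zip(widths, widths[1:]))


class TestEndToEnd:
    def test_self_reference_gives_vacuum(self, clean_pulse):
        ref = ts.add_noise(clean_pulse, 1e6, 5)
        oc = ts.extract_optical_constants(ref, ref, 1.11, floor_db=40)
        m = in_instrument_band(oc)
        np.testing.assert_allclose(oc.n[m], 1.0, atol=1e-9)
        np.testing.assert_allclose(oc.alpha_cm[m], 0.0, atol=1e-9)

    def test_round_trip_recovers_model_constants(self, clean_pulse):
        """Extraction inverts the forward model: n to 1e-3 absolute and
        alpha to 2% relative (where alpha > 5 cm^-1) at SNR 1e4."""
        rng_osc = (
            ts.LorentzOscillator(nu0=1.1, strength=0.003, gamma=0.05),
            ts.LorentzOscillator(nu0=2.1, strength=0.002, gamma=0.05),
        )
        model = ts.MaterialModel(eps_inf=1.42**2, oscillators=rng_osc)
        geom = ts.SampleGeometry(d_mm=1.11)
        sam = ts.add_noise(ts.transmit(clean_pulse, model, geom), 1e4, 11)
        ref = ts.add_noise(clean_pulse, 1e4, 12)
        oc = ts.extract_optical_constants(sam, ref, geom.d_mm, floor_db=40)
        m = in_instrument_band(oc)
        ncplx = ts.refractive_index_model(model, oc.nu[m])
        alpha_true = 2 * (2 * np.pi * oc.nu[m] * 1e12) * ncplx.imag / 2.99792458e10
        assert np.max(np.abs(oc.n[m] - ncplx.real)) < 1e-3
        big = alpha_true > 5.0
        rel = np.abs(oc.alpha_cm[m][big] - alpha_true[big]) / alpha_true[big]
        assert np.max(rel) < 0.02

    def test_noise_free_limit_exact_inversion(self, clean_pulse):
        """sup-norm n error shrinks toward zero as SNR grows (1e8 check)."""
        model, geom = ts.preset("mannitol_solid")
        sam = ts.add_noise(ts.transmit(clean_pulse, model, geom), 1e8, 21)
        ref = ts.add_noise(clean_pulse, 1e8, 22)
        oc = ts.extract_optical_constants(sam, ref, geom.d_mm, floor_db=40)
        m = in_instrument_band(oc)
        n_true = ts.refractive_index_model(model, oc.nu[m]).real
        assert np.max(np.abs(oc.n[m] - n_true)) < 1e-3

    def test_pad_factor_grid_stability(self, clean_pulse):
        model, geom = ts.preset("erythritol_solid")
        sam = ts.transmit(clean_pulse, model, geom)
        oc4 = ts.extract_optical_constants(sam, clean_pulse, geom.d_mm, pad_factor=4)
        oc8 = ts.extract_optical_constants(sam, clean_pulse, geom.d_mm, pad_factor=8)
        m4 = in_instrument_band(oc4)
        idx = np.searchsorted(oc8.nu, oc4.nu[m4])
        assert np.max(np.abs(oc8.n[idx] - oc4.n[m4])) < 1e-4

    def test_mismatched_time_axes_rejected(self, clean_pulse):
        other = ts.generate_reference_pulse(n_points=1024, snr=float("inf"), seed=None)
        with pytest.raises(ts.IncompatibleSpectraError):
            ts.extract_optical_constants(other, clean_pulse, 1.11)
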