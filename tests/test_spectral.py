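import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radarvitals.simulate import DisplacementTrace, TimeBase
from radarvitals.spectral import (
    BandConfig,
    average_abs_error,
    error_report,
    estimate_rates,
    fft_spectrum,
    highpass_heartbeat,
    ndct,
    ndct_direct,
    rate_error,
)

FS = 100.0
M_FULL = 2**17


class TestNDCT:
    def test_zero_signal_has_zero_spectrum(self):
        spec = ndct(np.zeros(64), FS, 256)
        np.testing.assert_array_equal(spec.values, 0.0)
        assert len(spec.freqs) == 129

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        L=st.integers(min_value=2, max_value=64),
        log_m=st.integers(min_value=7, max_value=9),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_fast_path_equals_direct_cosine_sum(self, L, log_m, seed):
        """The rfft-based evaluation is algebraically identical to the
        direct cosine projection, bin by bin."""
        rng = np.random.default_rng(seed)
        z = rng.normal(size=L)
        fast = ndct(z, FS, 2**log_m)
        direct = ndct_direct(z, FS, 2**log_m)
        np.testing.assert_allclose(
            fast.values, direct.values, rtol=1e-9, atol=1e-9 * max(1.0, np.abs(z).sum())
        )

    def test_even_phased_tone_peaks_near_line(self):
        """A cosine tone's peak sits at its frequency up to the finite-window
        bias (~4 bins for 2 cycles at L=500), far inside one percent."""
        t = np.arange(500) / FS
        spec = ndct(np.cos(2 * np.pi * 0.4 * t), FS, M_FULL)
        f, _ = spec.peak_in_band((0.05, 0.6))
        assert f == pytest.approx(0.4, abs=0.004)

    def test_length_and_power_of_two_validation(self):
        with pytest.raises(ValueError, match="M"):
            ndct(np.zeros(600), FS, 512)
        with pytest.raises(ValueError, match="power of two"):
            ndct(np.zeros(100), FS, 300)

    def test_grid_refinement_improves_peak_location(self):
        """From M=2^9 to 2^17 the peak error of an off-grid tone drops from
        grid-limited (~fs/M) to the windowing-bias floor."""
        t = np.arange(500) / FS
        z = np.cos(2 * np.pi * 0.37 * t)
        errs = [
            abs(ndct(z, FS, 2**e).peak_in_band((0.05, 0.6))[0] - 0.37)
            for e in range(9, 18)
        ]
        assert all(err <= FS / 2**9 for err in errs)
        assert errs[-1] < errs[0]
        assert errs[-1] <= 0.002  # bias floor, ~2 bins of 2^17 above it

    def test_scale_equivariance(self, study_residual):
        z = study_residual.samples
        a = ndct(z, FS, 2**12)
        b = ndct(3.5 * z, FS, 2**12)
        np.testing.assert_allclose(b.values, 3.5 * a.values, rtol=1e-9, atol=1e-12)


class TestFFTSpectrum:
    def test_tone_on_grid_occupies_single_bin(self):
        L = 512
        f0 = 10 * FS / L
        t = np.arange(L) / FS
        spec = fft_spectrum(np.cos(2 * np.pi * f0 * t), FS, L)
        nz = np.nonzero(spec.values > 1e-8 * spec.values.max())[0]
        assert list(nz) == [10]

    def test_ndct_main_lobe_narrower_than_fft(self, study_residual):
        """The cosine projection's implicit even extension doubles the
        effective window, halving the respiration main lobe."""
        z = study_residual.samples

        def halfmax_width(spec):
            mask = (spec.freqs >= 0.05) & (spec.freqs <= 0.6)
            f, v = spec.freqs[mask], spec.values[mask]
            k = int(np.argmax(v))
            above = v >= v[k] / 2
            i = k
            while i > 0 and above[i]:
                i -= 1
            j = k
            while j < len(v) - 1 and above[j]:
                j += 1
            return f[j] - f[i]

        w_ndct = halfmax_width(ndct(z, FS, M_FULL))
        w_fft = halfmax_width(fft_spectrum(z, FS, M_FULL))
        assert w_ndct <= w_fft
        assert w_ndct <= 0.6 * w_fft  # roughly the factor-2 narrowing


class TestHighpass:
    def test_dc_is_deeply_attenuated(self):
        out = highpass_heartbeat(np.ones(1000), FS)
        # the equiripple stopband floor sits exactly at the 40 dB design point
        assert np.sqrt(np.mean(out[200:-200] ** 2)) <= 1.01e-2

    def test_band_edges_meet_design(self):
        """0.4 Hz (respiration) drops by >= 40 dB; 1.3 Hz (heartbeat)
        passes within ~1 dB, both measured on the zero-phase response."""
        import scipy.signal

        from radarvitals.spectral import _design_highpass

        sos = _design_highpass(FS, BandConfig())
        w, h = scipy.signal.sosfreqz(sos, worN=[0.4, 1.3], fs=FS)
        resp_gain_db = 40 * np.log10(np.abs(h[0]))  # x2 for forward-backward
        heart_gain = np.abs(h[1]) ** 2
        assert resp_gain_db <= -40.0
        assert 0.88 <= heart_gain <= 1.12

    def test_heartbeat_tone_survives_respiration_removed(self):
        t = np.arange(500) / FS
        z = 3 * np.cos(2 * np.pi * 0.4 * t) + 1 * np.cos(2 * np.pi * 1.3 * t)
        out = highpass_heartbeat(z, FS)
        spec = ndct(out, FS, M_FULL)
        f, _ = spec.peak_in_band((0.8, 3.0))
        assert f == pytest.approx(1.3, abs=0.01)
        # respiration all but gone
        resp_peak = spec.peak_in_band((0.05, 0.6))[1]
        heart_peak = spec.peak_in_band((0.8, 3.0))[1]
        assert resp_peak <= 0.05 * heart_peak

    def test_too_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            highpass_heartbeat(np.zeros(100), 1.5)


class TestRateEstimation:
    def test_two_tone_rates_within_one_bin_on_long_window(self):
        """With 20+ s of data the windowing bias falls below the fine grid
        spacing and both rates are exact to one bin."""
        L = 2048
        t = np.arange(L) / FS
        z = DisplacementTrace(
            3 * np.cos(2 * np.pi * 0.3 * t) + 1 * np.cos(2 * np.pi * 1.5 * t),
            TimeBase(L, FS),
        )
        est = estimate_rates(z, method="NDCT", M=M_FULL)
        assert abs(est.rr - 0.3) <= FS / M_FULL
        assert abs(est.hr - 1.5) <= FS / M_FULL

    def test_single_tone_respiration(self):
        t = np.arange(500) / FS
        z = DisplacementTrace(np.cos(2 * np.pi * 0.5 * t), TimeBase(500, FS))
        est = estimate_rates(z, method="NDCT", M=M_FULL)
        assert est.rr == pytest.approx(0.5, abs=0.005)

    def test_rates_invariant_to_amplitude_scale(self, study_residual):
        a = estimate_rates(study_residual, M=2**14)
        scaled = DisplacementTrace(7.0 * study_residual.samples, study_residual.timebase)
        b = estimate_rates(scaled, M=2**14)
        assert a.rr == b.rr and a.hr == b.hr
        assert b.rr_peak_value == pytest.approx(7.0 * a.rr_peak_value, rel=1e-12)

    def test_short_window_rejected(self):
        z = DisplacementTrace(np.zeros(200), TimeBase(200, FS))
        with pytest.raises(ValueError, match="3 s"):
            estimate_rates(z)


class TestErrorMetrics:
    @pytest.mark.parametrize(
        "measured, reference, expected",
        [(0.4, 0.4, 0.0), (0.393, 0.4, -1.75), (0.646, 0.4, 61.5)],
    )
    def test_signed_percentage_error(self, measured, reference, expected):
        assert rate_error(measured, reference) == pytest.approx(expected, abs=5e-3)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            rate_error(0.4, 0.0)

    @pytest.mark.parametrize(
        "errors, expected",
        [
            ([61.50, 10.17, 13.71, -16.75], 25.53),
            ([2.39, 0.99, -1.07, -0.55], 1.25),
            ([0.0, 0.0, 0.0, 0.0], 0.0),
        ],
    )
    def test_mean_absolute_error(self, errors, expected):
        assert average_abs_error(errors) == pytest.approx(expected, abs=5e-3)

    def test_empty_error_sequence_rejected(self):
        with pytest.raises(ValueError):
            average_abs_error([])

    def test_error_report_combines_both(self):
        rep = error_report([0.393, 0.402], [0.4, 0.4])
        assert rep.per_part_errors[0] == pytest.approx(-1.75, abs=5e-3)
        assert rep.average_error == pytest.approx((1.75 + 0.5) / 2, abs=5e-3)
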