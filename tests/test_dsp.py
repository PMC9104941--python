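"""Phase-processing chain: range FFT through rate estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from radarvitals import dsp, forward_model as fm
from radarvitals.errors import AliasingError, InvalidArgumentError, NoTargetError


def make_phase(values, rate=20.0):
    return dsp.PhaseSeries(np.asarray(values, dtype=float), rate)


class TestRangeFFT:
    def test_zero_cube_gives_zero_matrix(self, chirp):
        cube = fm.IFDataCube(
            np.zeros((chirp.n_chirps, chirp.n_fast), dtype=complex), chirp
        )
        assert np.all(dsp.range_fft(cube) == 0)

    def test_bin_centred_tone_dominates(self, chirp):
        k = np.arange(chirp.n_fast)
        tone = np.exp(2j * np.pi * 10 * k / chirp.n_fast)
        cube = fm.IFDataCube(
            np.tile(tone, (chirp.n_chirps, 1)), chirp
        )
        profile = dsp.range_fft(cube)
        mags = np.abs(profile[:, 0])
        order = np.argsort(mags)
        assert order[-1] == 10
        assert mags[order[-1]] / mags[order[-2]] >= 10

    def test_parseval_per_column(self, chirp, default_scenario):
        cube = fm.simulate_observation(default_scenario, chirp, seed=0)
        full = np.fft.fft(cube.samples, axis=1)
        assert np.allclose(
            np.sum(np.abs(cube.samples) ** 2, axis=1),
            np.sum(np.abs(full) ** 2, axis=1) / chirp.n_fast,
            rtol=1e-9,
        )


class TestSelectRangeBin:
    def test_ties_break_to_smaller_bin(self):
        m = np.zeros((12, 4))
        m[5] = 1.0
        m[9] = 1.0
        assert dsp.select_range_bin(m, min_bin=0) == 5

    def test_min_bin_excludes_dc_leakage(self):
        m = np.zeros((12, 4))
        m[0] = 100.0
        m[7] = 1.0
        assert dsp.select_range_bin(m, min_bin=2) == 7

    def test_all_zero_profile_raises(self):
        with pytest.raises(NoTargetError):
            dsp.select_range_bin(np.zeros((8, 4)))


class TestExtractUnwrap:
    def test_unit_entries_give_zero_phase(self):
        m = np.ones((3, 16), dtype=complex)
        assert np.all(dsp.extract_phase(m, 1, 20.0).values == 0)

    def test_negative_real_axis_maps_to_plus_pi(self):
        m = np.full((1, 16), -1 + 0j)
        assert np.all(dsp.extract_phase(m, 0, 20.0).values == math.pi)

    def test_sinusoidal_displacement_peak_to_peak(self, chirp):
        """1 mm displacement sine -> unwrapped phase swing 8*pi*1e-3/lambda."""
        t = np.arange(chirp.n_chirps) / chirp.slow_rate
        disp = 0.5 + 0.001 * np.sin(2 * np.pi * 0.3 * t)
        cube = fm.synthesize_if_cube(disp, chirp)
        phase = dsp.extract_phase(dsp.range_fft(cube), 13, chirp.slow_rate)
        unwrapped = dsp.unwrap_phase(phase)
        expected = 8 * math.pi * 0.001 / chirp.wavelength
        assert np.ptp(unwrapped.values) == pytest.approx(expected, rel=0.01)

    def test_unwrap_recovers_wrapped_ramp(self):
        ramp = np.linspace(0.0, 10.0, 100)
        wrapped = np.angle(np.exp(1j * ramp))
        out = dsp.unwrap_phase(make_phase(wrapped)).values
        assert np.allclose(out - out[0], ramp - ramp[0], atol=1e-9)

    def test_unwrap_constant_unchanged(self):
        const = np.full(50, 1.3)
        assert np.array_equal(dsp.unwrap_phase(make_phase(const)).values, const)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_wrap_of_unwrap_is_wrap(self, seed):
        values = np.random.default_rng(seed).uniform(-10, 10, 64)
        unwrapped = dsp.unwrap_phase(make_phase(values)).values
        assert np.allclose(
            np.angle(np.exp(1j * unwrapped)), np.angle(np.exp(1j * values)), atol=1e-9
        )


class TestBandpass:
    def test_cardiac_band_passes_in_band_tone(self):
        t = np.arange(512) / 20.0
        x = make_phase(np.sin(2 * np.pi * 1.3 * t))
        out = dsp.bandpass_cascade(x, "cardiac")
        assert np.std(out.values) >= 0.6 * np.std(x.values)

    def test_breathing_band_rejects_cardiac_tone(self):
        t = np.arange(512) / 20.0
        x = make_phase(np.sin(2 * np.pi * 1.3 * t))
        out = dsp.bandpass_cascade(x, "breathing")
        assert np.std(out.values) <= 0.1 * np.std(x.values)

    def test_zero_in_zero_out(self):
        out = dsp.bandpass_cascade(make_phase(np.zeros(64)), "cardiac")
        assert np.all(out.values == 0)

    def test_rate_below_nyquist_raises(self):
        with pytest.raises(AliasingError):
            dsp.bandpass_cascade(make_phase(np.zeros(64), rate=3.0), "cardiac")

    @pytest.mark.parametrize("band,edges", [("cardiac", (0.8, 2.0)), ("breathing", (0.1, 0.5))])
    def test_frequency_response_contract(self, band, edges):
        """Passband centre within [-3, +0.5] dB; >= 20 dB one octave out."""
        lo, hi = edges
        sos = dsp._design_cascade(lo, hi, 20.0)
        centre = math.sqrt(lo * hi)
        freqs = np.array([lo / 2, centre, hi * 2])
        _, h = sps.sosfreqz(sos, worN=2 * np.pi * freqs / 20.0)
        db = 20 * np.log10(np.abs(h))
        assert -3.0 <= db[1] <= 0.5
        assert db[0] <= -20.0 and db[2] <= -20.0

    def test_output_length_preserved(self):
        x = make_phase(np.random.default_rng(0).normal(size=173))
        assert len(dsp.bandpass_cascade(x, "breathing").values) == 173


class TestMotionDenoise:
    def test_all_zero_series_keeps_everything(self):
        masked = dsp.motion_denoise(make_phase(np.zeros(100)))
        assert masked.discarded_windows == []
        assert masked.sample_mask.all()

    def test_quarter_radian_window_discarded(self):
        """A window of constant 0.25 rad has energy 0.0625 > 0.04."""
        values = np.zeros(100)
        values[40:60] = 0.25
        masked = dsp.motion_denoise(make_phase(values))
        assert masked.discarded_windows == [(2.0, 3.0)]
        assert not masked.sample_mask[40:60].any()

    def test_small_sinusoid_fully_retained(self):
        """Amplitude 0.2 rad -> mean square 0.02 < E_th."""
        t = np.arange(200) / 20.0
        masked = dsp.motion_denoise(make_phase(0.2 * np.sin(2 * np.pi * 1.0 * t)))
        assert masked.discarded_windows == []

    def test_energy_is_mean_square_per_window(self):
        values = np.concatenate([np.full(20, 0.1), np.full(20, 0.3)])
        masked = dsp.motion_denoise(make_phase(values))
        assert masked.window_energies == pytest.approx([0.01, 0.09])
        assert masked.discarded_windows == [(1.0, 2.0)]


def pulse_train(rate=20.0, period=1.0, duration=25.0, phase_offset=0.2):
    t = np.arange(int(duration * rate)) / rate
    values = np.zeros_like(t)
    for centre in np.arange(phase_offset, duration, period):
        values += np.exp(-0.5 * ((t - centre) / 0.05) ** 2)
    return t, values


class TestAdaptivePeaks:
    def test_uniform_train_keeps_all_peaks(self):
        _, values = pulse_train()
        series = make_phase(values)
        masked = dsp.motion_denoise(series, e_th=1e9)
        result = dsp.detect_peaks_adaptive(masked)
        assert result.flag is dsp.QualityFlag.OK
        assert len(result.times) == 25  # zero variance: nothing rejected

    def test_spurious_peak_rejected(self):
        t, values = pulse_train()
        spur = np.exp(-0.5 * ((t - (5.2 + 0.15)) / 0.02) ** 2)
        series = make_phase(values + spur)
        masked = dsp.motion_denoise(series, e_th=1e9)
        result = dsp.detect_peaks_adaptive(masked)
        assert not np.any(np.abs(result.times - 5.35) < 0.05)

    def test_all_negative_series_flags_insufficient(self):
        # small negative values: below E_th (windows retained) yet no
        # positive local maxima exist -> insufficient peaks, not an error
        values = -0.05 - 0.02 * np.sin(np.arange(100))
        masked = dsp.motion_denoise(make_phase(values))
        assert masked.sample_mask.all()
        result = dsp.detect_peaks_adaptive(masked)
        assert result.flag is dsp.QualityFlag.INSUFFICIENT_PEAKS

    def test_fully_masked_series_flags_all_discarded(self):
        masked = dsp.motion_denoise(make_phase(np.full(100, 5.0)))
        result = dsp.detect_peaks_adaptive(masked)
        assert result.flag is dsp.QualityFlag.ALL_DISCARDED

    def test_no_accepted_peak_inside_discarded_window(self):
        scenario = fm.DisplacementScenario(rbm_events=((10.0, 1.5, 0.01),))
        cube = fm.simulate_observation(scenario, seed=5)
        est = dsp.process_cube(cube)
        assert len(est.discarded_windows) >= 1
        for start, stop in est.discarded_windows:
            for t in np.concatenate([est.hr_peak_times, est.br_peak_times]):
                assert not (start < t < stop)


class TestEstimateRate:
    def test_one_per_second_is_sixty(self):
        rate, flag = dsp.estimate_rate(np.arange(0.0, 26.0, 1.0))
        assert rate == pytest.approx(60.0)
        assert flag is dsp.QualityFlag.OK

    def test_point_75_second_interval_is_eighty(self):
        rate, _ = dsp.estimate_rate(np.arange(0.0, 24.0, 0.75))
        assert rate == pytest.approx(80.0)

    def test_too_few_peaks_flagged(self):
        rate, flag = dsp.estimate_rate([1.0])
        assert rate == 0.0
        assert flag is dsp.QualityFlag.INSUFFICIENT_PEAKS


class TestEndToEnd:
    def test_default_scenario_recovers_both_rates(self, default_scenario):
        est = dsp.process_cube(fm.simulate_observation(default_scenario, seed=1))
        assert est.hr_bpm == pytest.approx(72.0, abs=2.0)
        assert est.br_bpm == pytest.approx(18.0, abs=1.0)
        assert est.quality_flag is dsp.QualityFlag.OK

    def test_causal_mode_available(self, default_scenario):
        est = dsp.process_cube(
            fm.simulate_observation(default_scenario, seed=1), zero_phase=False
        )
        assert est.hr_bpm == pytest.approx(72.0, abs=3.0)
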