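import numpy as np
import pytest
from scipy import signal as sp_signal

from caepdetect.signal_model import ContinuousRecording, EpochEnsemble, FilterSpec
from caepdetect.simulate import (
    ARModel,
    CAEPTemplate,
    SimulationConfig,
    ar_noise,
    default_ar_presets,
    default_templates,
    estimate_snr,
    fit_ar_yw,
    scale_template,
    simulate_ensemble,
    synth_template,
)

FS = 500.0


class TestFitARYuleWalker:
    def test_recovers_ar1_coefficient(self, rng):
        model = ARModel(coefficients=[0.9], innovation_sd=1.0)
        x = ar_noise(model, 100000, rng)
        fit = fit_ar_yw(x, order=1)
        assert fit.coefficients[0] == pytest.approx(0.9, abs=0.02)

    def test_white_noise_fits_near_zero(self, rng):
        x = ContinuousRecording(rng.standard_normal(100000) * 2.0, FS)
        fit = fit_ar_yw(x, order=5)
        assert np.max(np.abs(fit.coefficients)) < 0.02
        assert fit.innovation_sd == pytest.approx(2.0, rel=0.02)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            fit_ar_yw(np.full(5000, 3.0), order=2)

    def test_nonstationary_model_rejected(self):
        with pytest.raises(ValueError):
            ARModel(coefficients=[1.01], innovation_sd=1.0)


class TestARNoise:
    def test_ar1_lag1_autocorrelation(self, rng):
        model = ARModel(coefficients=[0.9], innovation_sd=1.0)
        x = ar_noise(model, 100000, rng).samples
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(0.9, abs=0.01)

    def test_zero_innovation_gives_zero_output(self, rng):
        model = ARModel(coefficients=[0.5], innovation_sd=0.0)
        assert np.all(ar_noise(model, 1000, rng).samples == 0)

    def test_spectrum_matches_analytic_psd(self, rng):
        from caepdetect.fdb import welch_psd

        model = ARModel(coefficients=[1.2, -0.6], innovation_sd=1.5)
        x = ar_noise(model, 400000, rng, fs=FS)
        est = welch_psd(x, 2.0)
        ref = model.psd(est.freqs[1:-1], FS)
        ratio = est.values[1:-1] / ref
        assert np.median(ratio) == pytest.approx(1.0, abs=0.05)
        assert np.all(np.abs(np.log(ratio)) < 0.5)


class TestPresets:
    def test_presets_are_stationary_order_20(self):
        presets = default_ar_presets()
        assert len(presets) >= 5
        for m in presets:
            assert m.order == 20
            roots = np.abs(np.roots(m.a_poly()))
            assert np.all(roots < 1.0)

    def test_filtered_power_concentrated_below_10hz(self):
        freqs = np.linspace(0.01, FS / 2, 3000)
        sos = FilterSpec().sos(FS)
        _, h = sp_signal.sosfreqz(sos, worN=2 * np.pi * freqs / FS)
        gain = np.abs(h) ** 4  # zero-phase application squares the response
        for m in default_ar_presets():
            psd = m.psd(freqs, FS) * gain
            frac = np.trapezoid(psd[freqs < 10], freqs[freqs < 10]) / np.trapezoid(psd, freqs)
            assert frac > 0.8, m.label

    def test_presets_deterministic_across_calls(self):
        a = default_ar_presets()
        b = default_ar_presets()
        for m1, m2 in zip(a, b):
            assert np.array_equal(m1.coefficients, m2.coefficients)


class TestTemplates:
    def test_single_peak_location_and_height(self):
        tpl = synth_template([(200.0, 5.0, 40.0)], fs=FS)
        i = np.argmax(tpl.waveform)
        assert i * 1000.0 / FS == pytest.approx(200.0, abs=2.0)
        assert tpl.waveform[i] == pytest.approx(5.0, rel=1e-6)

    def test_biphasic_has_zero_crossing_between_peaks(self):
        tpl = synth_template([(150.0, 5.0, 30.0), (400.0, -4.0, 50.0)], fs=FS)
        segment = tpl.waveform[int(0.150 * FS) : int(0.400 * FS)]
        assert np.min(np.sign(segment[:-1]) * np.sign(segment[1:])) == -1 or np.any(segment == 0)

    def test_zero_amplitude_gives_zero_template(self):
        tpl = synth_template([(100.0, 0.0, 30.0)], fs=FS)
        assert np.all(tpl.waveform == 0)

    def test_latency_outside_window_raises(self):
        with pytest.raises(ValueError):
            synth_template([(800.0, 5.0, 30.0)], fs=FS, duration_ms=700.0)

    def test_template_library_fits_window(self):
        for tpl in default_templates(FS):
            assert tpl.waveform.size <= 350
            assert np.max(np.abs(tpl.waveform)) > 0


class TestSNR:
    def test_identical_epochs_give_zero_db(self, rng):
        row = rng.standard_normal(350)
        ens = EpochEnsemble(np.tile(row, (10, 1)), FS)
        assert estimate_snr(ens) == pytest.approx(0.0, abs=1e-10)

    def test_constructed_minus_10_db(self):
        # coherent-average power is 1/10 of the raw mean square when the two
        # epochs are s(1 + a) and s(a - 1) with a^2 = 1/9... solved: a = 1/3
        t = np.arange(350)
        s = np.sqrt(2.0) * np.sin(2 * np.pi * 5 * t / 350)  # mean square 1
        a = 1.0 / 3.0
        ens = EpochEnsemble(np.vstack([(1 + a) * s, (a - 1) * s]), FS)
        expected = 10 * np.log10(a**2 / (1 + a**2))
        assert estimate_snr(ens) == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(-10.0, abs=0.5)

    def test_zero_signal_raises(self):
        with pytest.raises(ValueError):
            estimate_snr(EpochEnsemble(np.zeros((3, 10)), FS))

    def test_pure_noise_snr_decreases_with_n(self, rng):
        data = rng.standard_normal((160, 350))
        small = estimate_snr(EpochEnsemble(data[:10], FS))
        large = estimate_snr(EpochEnsemble(data, FS))
        assert large < small < 0


class TestScaleTemplate:
    def test_minus_10_db_scale_factor(self):
        tpl = CAEPTemplate(np.ones(100), FS)  # mean power 1
        scaled = scale_template(tpl, noise_power=1.0, target_snr_db=-10.0)
        assert scaled.waveform[0] == pytest.approx(10 ** (-0.5))

    def test_equal_powers_at_zero_db(self):
        tpl = CAEPTemplate(np.full(50, 2.0), FS)
        scaled = scale_template(tpl, noise_power=4.0, target_snr_db=0.0)
        assert np.allclose(scaled.waveform, tpl.waveform)

    def test_doubling_noise_scales_by_sqrt2(self):
        tpl = CAEPTemplate(np.ones(10), FS)
        s1 = scale_template(tpl, 1.0, -6.0).waveform[0]
        s2 = scale_template(tpl, 2.0, -6.0).waveform[0]
        assert s2 / s1 == pytest.approx(np.sqrt(2.0))

    def test_zero_template_raises(self):
        with pytest.raises(ValueError):
            scale_template(CAEPTemplate(np.zeros(10), FS), 1.0, -10.0)


class TestSimulateEnsemble:
    def test_fixed_seed_reproduces_exactly(self):
        cfg = SimulationConfig(n_epochs=20, snr_db=-10)
        rec1, ens1 = simulate_ensemble(cfg, np.random.default_rng(5))
        rec2, ens2 = simulate_ensemble(cfg, np.random.default_rng(5))
        assert np.array_equal(rec1.samples, rec2.samples)
        assert np.array_equal(ens1.data, ens2.data)

    def test_geometry_of_standard_run(self, rng):
        cfg = SimulationConfig(n_epochs=20)
        rec, ens = simulate_ensemble(cfg, rng)
        assert ens.data.shape == (20, 350)
        assert rec.onsets.size == 20
        # ~1111 ms epochs at the 0.9 Hz stimulus rate
        assert cfg.geometry().epoch_samples == 555

    def test_template_injection_is_exactly_additive(self):
        tpl = synth_template([(250.0, 6.0, 80.0)], fs=FS)
        h0 = SimulationConfig(n_epochs=10, template=tpl)
        h1 = SimulationConfig(n_epochs=10, snr_db=-8, template=tpl)
        _, ens0 = simulate_ensemble(h0, np.random.default_rng(9))
        _, ens1 = simulate_ensemble(h1, np.random.default_rng(9))
        diff = ens1.data - ens0.data
        # every epoch receives the identical scaled waveform
        assert np.allclose(diff - diff[0], 0.0, atol=1e-9)
        assert np.corrcoef(diff[0], tpl.waveform)[0, 1] > 0.999

    def test_realized_snr_near_target(self, rng):
        # expected-power calibration is defined over the full epoch; realized
        # estimates scatter slightly above the target because the coherent
        # average retains ~1/N of the noise power
        from caepdetect.signal_model import epoch_recording

        cfg = SimulationConfig(n_epochs=160, snr_db=-12)
        values = []
        for _ in range(10):
            rec, _ = simulate_ensemble(cfg, rng)
            full = epoch_recording(rec, 1000.0 / cfg.stimulus_rate)
            values.append(estimate_snr(full))
        assert np.mean(values) == pytest.approx(-11.6, abs=1.0)

    def test_ar_recovery_from_simulated_noise(self, rng):
        # round trip through the generator: refit recovers the preset
        preset = default_ar_presets()[1]
        x = ar_noise(preset, 200000, rng)
        fit = fit_ar_yw(x, order=20)
        assert np.max(np.abs(fit.coefficients - preset.coefficients)) < 0.05
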