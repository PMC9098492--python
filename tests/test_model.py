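"""Cascade model stages: linear dynamics, envelope, gain control, fits, VAF."""

import numpy as np
import pytest

import vestcode as vc
from vestcode.model import (
    OutputPolynomial,
    fit_output_nonlinearity,
    tc_pre_nonlinearity,
    transfer_function,
)


class TestLinearDynamics:
    def test_sinusoid_matches_closed_form(self):
        stim = vc.generate_sinusoid(1.0, 1.0, 30.0)
        out = vc.apply_linear_dynamics(stim)
        T = transfer_function(1.0)
        core = out[5000:-5000]
        assert np.abs(core).max() == pytest.approx(abs(T), rel=1e-3)
        g, p = vc.gain_phase_xcorr(vc.RateSequence(out), stim)
        assert p == pytest.approx(np.degrees(np.angle(T)), abs=0.5)

    def test_dc_input_maps_to_zero(self):
        flat = vc.HeadVelocityTrace(np.full(10_000, 25.0))
        out = vc.apply_linear_dynamics(flat)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_linearity_in_k(self, naturalistic_60s):
        base = vc.apply_linear_dynamics(naturalistic_60s)
        doubled = vc.apply_linear_dynamics(
            naturalistic_60s, vc.LinearDynamicsParams(k=2 * 1.7207))
        assert np.allclose(doubled, 2 * base, rtol=1e-9, atol=1e-9)

    def test_default_constants(self):
        p = vc.LinearDynamicsParams()
        assert (p.k, p.T1, p.T2, p.Tc) == (1.7207, 0.06, 0.0006, 5.7)


class TestHilbertDecomposition:
    def test_pure_tone_envelope(self):
        stim = vc.generate_sinusoid(8.0, 15.0, 10.0)
        dec = vc.hilbert_decompose(stim)
        core = dec.amplitude[100:-100]
        assert np.all(np.abs(core - 15.0) < 0.02 * 15.0)

    def test_ramp_envelope_tracked(self):
        ramp = vc.generate_ramp(4.0, 100.0, 50.0)
        dec = vc.hilbert_decompose(ramp)
        from vestcode.stimuli import ramp_envelope

        expected = ramp_envelope(ramp.times, 100.0, 50.0)
        core = slice(2000, -2000)
        assert np.abs(dec.amplitude[core] - expected[core]).max() < 5.0

    def test_zero_trace(self):
        dec = vc.hilbert_decompose(np.zeros(5000))
        assert np.allclose(dec.amplitude, 0.0)

    def test_instantaneous_frequency_of_tone(self):
        stim = vc.generate_sinusoid(5.0, 10.0, 10.0)
        dec = vc.hilbert_decompose(stim)
        assert np.median(dec.instantaneous_frequency) == pytest.approx(5.0, rel=1e-3)


class TestContrastGainControl:
    def test_constant_amplitude_gives_lorentzian_gain(self):
        gp = vc.GainControlParams()
        stim = vc.generate_sinusoid(2.0, 20.0, 20.0)
        out = vc.contrast_gain_scale(stim, gp)
        expected = gp.gain_at(20.0)
        core = slice(1000, -1000)
        ratio = out[core] / np.where(stim.samples[core] == 0, np.nan, stim.samples[core])
        assert np.nanmedian(ratio) == pytest.approx(expected, rel=0.02)

    def test_zero_amplitude_limit_is_p1(self):
        gp = vc.GainControlParams()
        assert gp.gain_at(0.0) == pytest.approx(2.0)

    def test_p2_zero_reduces_to_pure_scaling(self, naturalistic_60s):
        gp = vc.GainControlParams(P1=2.0, P2=0.0)
        out = vc.contrast_gain_scale(naturalistic_60s, gp)
        assert np.allclose(out, 2.0 * naturalistic_60s.samples)

    def test_gain_strictly_decreasing_in_amplitude(self):
        gp = vc.GainControlParams()
        amps = np.linspace(0, 200, 50)
        g = gp.gain_at(amps)
        assert np.all(np.diff(g) < 0)
        assert g[0] == pytest.approx(gp.P1)


class TestSigmoid:
    def test_fixed_points_and_symmetry(self):
        assert vc.sigmoid(0.0) == pytest.approx(0.0)
        assert vc.sigmoid(10.0) == pytest.approx(-25 + 50 / (1 + np.exp(-1.0)))
        x = np.linspace(-80, 80, 41)
        assert np.allclose(vc.sigmoid(x) + vc.sigmoid(-x), 0.0, atol=1e-12)

    def test_bounded_and_monotone(self):
        x = np.linspace(-300, 300, 601)
        y = vc.sigmoid(x)
        assert np.all(y > -25) and np.all(y < 25)
        assert np.all(np.diff(vc.sigmoid(np.linspace(-500, 500, 1001))) >= 0)

    def test_inverse_roundtrip(self):
        from vestcode.model import sigmoid_inverse

        x = np.linspace(-60, 60, 121)
        assert np.allclose(sigmoid_inverse(vc.sigmoid(x)), x, atol=1e-6)


class TestSimulateVN:
    def test_gain_and_phase_increase_with_frequency(self, vn_params):
        gains, phases = [], []
        for f in (0.5, 1, 2, 3, 4, 5, 8, 17):
            stim = vc.generate_sinusoid(f, 15.0, 20.0)
            rate = vc.simulate_vn(stim, vn_params)
            g, p = vc.gain_phase_xcorr(rate, stim)
            gains.append(g)
            phases.append(p)
        assert np.all(np.diff(gains) > 0)
        assert np.all(np.diff(phases) > 0)

    def test_conditions_share_frequency_response(self, vn_params, naturalistic_300s):
        """Without gain control the cascade responds alike to both stimulus classes."""
        fr = vc.gain_phase_spectral(
            vc.simulate_vn(naturalistic_300s, vn_params), naturalistic_300s)
        for i, f in enumerate(fr.frequencies):
            stim = vc.generate_sinusoid(f, 15.0, 20.0)
            g, p = vc.gain_phase_xcorr(vc.simulate_vn(stim, vn_params), stim)
            assert fr.phase[i] == pytest.approx(p, abs=12.0)
            assert 0.4 < fr.gain[i] / g < 1.6  # sigmoid compression differs mildly

    def test_zero_stimulus_rests(self, vn_params):
        flat = vc.HeadVelocityTrace(np.zeros(5000))
        rate = vc.simulate_vn(flat, vn_params)
        assert np.allclose(rate.samples, vn_params.resting_rate)


class TestSimulateTC:
    def test_sinusoid_gain_phase_increase(self, tc_params):
        gains, phases = [], []
        for f in (0.5, 2, 5, 17):
            stim = vc.generate_sinusoid(f, 15.0, 20.0)
            g, p = vc.gain_phase_xcorr(vc.simulate_tc(stim, tc_params), stim)
            gains.append(g)
            phases.append(p)
        assert np.all(np.diff(gains) > 0) and np.all(np.diff(phases) > 0)

    def test_p2_zero_matches_scaled_vn(self, naturalistic_60s):
        tc = vc.NeuronModelParams.tc(vc.GainControlParams(P1=1.0, P2=0.0))
        vn = vc.NeuronModelParams.vn()
        a = vc.simulate_tc(naturalistic_60s, tc)
        b = vc.simulate_vn(naturalistic_60s, vn)
        assert np.allclose(a.samples, b.samples, atol=1e-9)

    def test_gain_control_compresses_large_amplitudes(self, tc_params, vn_params):
        loud = vc.generate_sinusoid(2.0, 100.0, 20.0)
        g_tc, _ = vc.gain_phase_xcorr(vc.simulate_tc(loud, tc_params), loud)
        quiet = vc.generate_sinusoid(2.0, 10.0, 20.0)
        g_tc_quiet, _ = vc.gain_phase_xcorr(vc.simulate_tc(quiet, tc_params), quiet)
        assert g_tc < g_tc_quiet  # hallmark of contrast gain control


class TestLorentzianFit:
    def test_noiseless_roundtrip_to_4_significant_figures(self):
        gp = vc.GainControlParams()
        A = np.arange(0.0, 101.0, 10.0)
        fit, resid = vc.fit_lorentzian(A, gp.gain_at(A))
        assert fit.P1 == pytest.approx(2.0, rel=1e-4)
        assert fit.P2 == pytest.approx(0.037, rel=1e-4)
        assert resid < 1e-8

    def test_constant_gains_degenerate_fit(self):
        fit, _ = vc.fit_lorentzian(np.array([0.0, 50.0, 100.0]), np.full(3, 1.5))
        assert fit.P1 == pytest.approx(1.5, rel=1e-3)
        assert fit.P2 == pytest.approx(0.0, abs=1e-4)

    def test_recovery_under_multiplicative_noise(self, rng):
        gp = vc.GainControlParams()
        A = np.linspace(0, 100, 50)
        noisy = gp.gain_at(A) * (1 + 0.05 * rng.standard_normal(50))
        fit, _ = vc.fit_lorentzian(A, noisy)
        assert fit.P1 == pytest.approx(2.0, rel=0.10)
        assert fit.P2 == pytest.approx(0.037, rel=0.10)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            vc.fit_lorentzian(np.array([-1.0, 2.0, 3.0]), np.ones(3))
        with pytest.raises(ValueError):
            vc.fit_lorentzian(np.array([1.0, 1.0, 1.0]), np.ones(3))


class TestOutputNonlinearity:
    def test_identity_mapping_recovered(self, rng):
        x = rng.uniform(-20, 20, 20_000)
        poly = fit_output_nonlinearity(x, x)
        grid = np.linspace(-19, 19, 100)
        assert np.abs(poly(grid) - grid).max() < 0.01 * 40

    def test_known_sigmoid_recovered(self, rng):
        x = rng.uniform(-30, 30, 50_000)
        y = vc.sigmoid(x) + 60.0
        poly = fit_output_nonlinearity(x, y)
        grid = np.linspace(-28, 28, 100)
        assert np.abs(poly(grid) - (vc.sigmoid(grid) + 60.0)).max() < 0.05 * 50

    def test_independent_target_gives_flat_map(self, rng):
        x = rng.uniform(-20, 20, 50_000)
        y = rng.normal(70, 5, 50_000)
        poly = fit_output_nonlinearity(x, y)
        grid = np.linspace(-19, 19, 100)
        assert np.abs(poly(grid) - 70.0).max() < 2.0

    def test_clamped_extrapolation(self, rng):
        x = rng.uniform(-10, 10, 10_000)
        poly = fit_output_nonlinearity(x, x**2)
        assert poly(1e6) == pytest.approx(poly(poly.domain[1]))

    def test_unfitted_is_identity(self):
        poly = OutputPolynomial()
        assert np.allclose(poly(np.array([-5.0, 0.0, 7.0])), [-5.0, 0.0, 7.0])


class TestVAF:
    def test_perfect_prediction(self, rng):
        x = rng.standard_normal(1000)
        assert vc.vaf(x, x) == pytest.approx(1.0)

    def test_constant_prediction_scores_zero(self, rng):
        x = rng.standard_normal(10_000)
        assert vc.vaf(np.full(10_000, x.mean()), x) == pytest.approx(0.0, abs=1e-12)

    def test_equal_variance_noise_scores_near_zero(self, rng):
        x = rng.standard_normal(200_000)
        pred = x + rng.standard_normal(200_000)
        assert vc.vaf(pred, x) == pytest.approx(0.0, abs=0.02)

    def test_model_self_consistency(self, tc_params, naturalistic_60s):
        rate = vc.simulate_tc(naturalistic_60s, tc_params)
        assert vc.vaf(rate, rate) == pytest.approx(1.0)

    def test_rejects_zero_variance_actual(self):
        with pytest.raises(ValueError):
            vc.vaf(np.ones(10), np.ones(10))


class TestSmallSignalLinearity:
    def test_tc_with_p2_zero_matches_linear_theory(self):
        """In the small-signal regime the cascade is LTI with gain P1*|T(f)|*SIG'(0)."""
        tc = vc.NeuronModelParams.tc(vc.GainControlParams(P1=1.0, P2=0.0))
        slope0 = 50.0 / 40.0
        for f in (1.0, 5.0):
            stim = vc.generate_sinusoid(f, 1.0, 30.0)  # |X| ~ |T(f)| <= 2 spk/s
            g, p = vc.gain_phase_xcorr(vc.simulate_tc(stim, tc), stim)
            T = transfer_function(f)
            assert g == pytest.approx(abs(T) * slope0, rel=0.02)
            assert p == pytest.approx(np.degrees(np.angle(T)), abs=2.0)


class TestRoundTrip:
    def test_ramp_profiles_recover_gain_control(self):
        """Simulated ramp responses, linearized window gains, Lorentzian fit: recovers (P1, P2)."""
        from vestcode.model import sigmoid_inverse

        truth = vc.GainControlParams(P1=2.0, P2=0.037)
        params = vc.NeuronModelParams.tc(truth)
        amps, gains = [], []
        for f in (0.5, 1, 2, 3, 4, 5, 8, 17):
            ramp = vc.generate_ramp(f, 100.0, 50.0)
            rate = vc.simulate_tc(ramp, params)
            linearized = sigmoid_inverse(rate.samples - np.mean(rate.samples))
            prof = vc.ramp_gain_profile(linearized, ramp, 4.0)
            t_mag = abs(transfer_function(f))
            amps.extend(prof.amplitude)
            gains.extend(prof.gain / t_mag)
        fit, _ = vc.fit_lorentzian(np.array(amps), np.array(gains))
        assert fit.P1 == pytest.approx(truth.P1, rel=0.10)
        assert fit.P2 == pytest.approx(truth.P2, rel=0.10)


class TestSerialization:
    def test_params_json_roundtrip(self, tmp_path, rng):
        x = rng.uniform(-20, 20, 10_000)
        poly = fit_output_nonlinearity(x, vc.sigmoid(x) + 60.0)
        nl = vc.model.StaticNonlinearities(output_poly=poly)
        params = vc.NeuronModelParams.tc(
            vc.GainControlParams(P1=1.8, P2=0.04), nonlinearities=nl,
            resting_rate=55.0)
        path = tmp_path / "params.json"
        params.to_json(path)
        back = vc.NeuronModelParams.from_json(path)
        assert back.gain_control == params.gain_control
        assert back.dynamics == params.dynamics
        assert back.resting_rate == 55.0
        grid = np.linspace(-15, 15, 50)
        assert np.allclose(back.nonlinearities.output_poly(grid), poly(grid))

    def test_vn_params_json_roundtrip(self):
        params = vc.NeuronModelParams.vn(resting_rate=48.0)
        back = vc.NeuronModelParams.from_json(params.to_json())
        assert back.neuron_class == "VN" and back.gain_control is None

    def test_rate_csv_roundtrip(self, tmp_path, rng):
        seq = vc.RateSequence(rng.uniform(0, 120, 5000))
        path = tmp_path / "rate.csv"
        seq.to_csv(path)
        back = vc.RateSequence.from_csv(path)
        assert np.allclose(back.samples, seq.samples, rtol=1e-5, atol=1e-3)
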