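import warnings

import numpy as np
import pytest

from ergpipe.core import InvalidArgumentError, RangeWarning, TimeSeries
from ergpipe.latency import cross_correlate, xcorr_latency
from ergpipe.spectral import estimate_spectra, gain_magnitude, resample_uniform
from ergpipe.filter_fit import model_gain
from ergpipe.stimulus import StimulusSpec, butterworth_lowpass, generate_white_noise
from ergpipe.synthetic import (CohortSpec, MemberParams, PhotoreceptorParams,
                               TemperatureModel, WALKING_EPOCH_PARAMS,
                               adaptation_latency, heating_protocol,
                               latency_from_temperature, null_protocol,
                               second_order_response, simulate_cohort,
                               simulate_session, tau_from_temperature,
                               walking_protocol)


class TestForwardModel:
    def test_dc_response_is_minus_beta(self):
        const = TimeSeries(np.full(3000, 2.0), 3000.0)
        p = PhotoreceptorParams(beta=1.5, tau=1.4, zeta=0.15, delay=8.0)
        out = second_order_response(const, p)
        assert np.allclose(out.samples, -1.5 * 2.0, atol=1e-9)

    def test_resonance_amplitude_ratio(self):
        """At the frequency where w*tau = 1 the gain magnitude is beta/(2*zeta)."""
        beta, tau, zeta = 1.0, 1.41, 0.15
        f0 = 1000.0 / (2 * np.pi * tau)  # w*tau = 1
        rate = 3000.0
        t = np.arange(0, 10, 1 / rate)
        probe = TimeSeries(np.sin(2 * np.pi * f0 * t), rate)
        out = second_order_response(probe, PhotoreceptorParams(beta=beta, tau=tau,
                                                               zeta=zeta, delay=0.0))
        amp = np.sqrt(2) * np.std(out.samples[3000:-3000])
        assert amp == pytest.approx(beta / (2 * zeta), rel=0.01)

    def test_empirical_gain_peak_location(self, bandlimited_noise):
        """Measured transfer of the simulated ERG peaks where |H| peaks
        (110.3 Hz for tau = 1.41 ms, zeta = 0.150)."""
        grid = np.arange(50.0, 200.0, 0.01)
        f_oracle = grid[np.argmax(model_gain(grid, 1.0, 1.41, 0.150))]
        assert f_oracle == pytest.approx(110.3, abs=0.05)
        p = PhotoreceptorParams(beta=1.0, tau=1.41, zeta=0.150, delay=8.0)
        erg = second_order_response(bandlimited_noise, p)
        est = estimate_spectra(resample_uniform(bandlimited_noise),
                               resample_uniform(erg))
        freqs, g = gain_magnitude(est)
        f_meas = freqs[np.argmax(g)]
        assert abs(f_meas - f_oracle) < 2.0

    def test_noiseless_gain_matches_model_to_220hz(self):
        """A long noiseless simulation reproduces |H(f)| within 2 % up to
        220 Hz through the full resample + spectral-estimation chain."""
        stim = butterworth_lowpass(generate_white_noise(30.0, 3000.0, seed=11))
        p = PhotoreceptorParams(beta=2.0, tau=1.41, zeta=0.150, delay=8.0)
        erg = second_order_response(stim, p)
        est = estimate_spectra(resample_uniform(stim), resample_uniform(erg))
        freqs, g = gain_magnitude(est)
        band = (freqs >= 5) & (freqs <= 220)
        expected = model_gain(freqs[band], 2.0, 1.41, 0.150)
        assert np.max(np.abs(g[band] - expected) / expected) < 0.02

    def test_unstable_tau_rejected(self):
        x = TimeSeries(np.zeros(100) + 1.0, 1000.0)
        with pytest.raises(InvalidArgumentError):
            second_order_response(x, PhotoreceptorParams(tau=0.2))


class TestTemperatureModels:
    def test_latency_linear_in_temperature(self):
        m = TemperatureModel()
        assert latency_from_temperature(30.0, m) == pytest.approx(22.21 - 0.48 * 30, abs=1e-9)
        assert latency_from_temperature(30.0, m) == pytest.approx(7.81, abs=1e-9)

    def test_zero_slope_is_temperature_independent(self):
        m = TemperatureModel(slope=0.0)
        assert (latency_from_temperature(25.0, m)
                == latency_from_temperature(35.0, m) == m.intercept)

    def test_out_of_range_warns(self):
        with pytest.warns(RangeWarning):
            latency_from_temperature(40.0)

    def test_tau_anchor_points_and_midpoint(self):
        m = TemperatureModel()
        assert tau_from_temperature(26.9, m) == pytest.approx(1.48, abs=1e-9)
        assert tau_from_temperature(31.9, m) == pytest.approx(1.14, abs=1e-9)
        assert tau_from_temperature(29.4, m) == pytest.approx(1.31, abs=1e-9)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(InvalidArgumentError):
            tau_from_temperature(60.0)


class TestSessions:
    def test_walking_temperature_rise(self):
        """The default walking protocol warms the eye by 2.3 degC over the
        active epoch, then decays back."""
        member = MemberParams(temp_rise=2.3, snr=4.0,
                              epoch_params=WALKING_EPOCH_PARAMS,
                              latency_targets={"before": 9.0, "active": 7.4,
                                               "after": 9.0})
        s = simulate_session(StimulusSpec(duration=10.0), member,
                             walking_protocol(before_s=20, active_s=20, after_s=30),
                             seed=6)
        temp = s.channels["temperature"]
        before = np.median(temp.crop(0, 20).samples)
        peak = np.median(temp.crop(39, 40).samples)
        end = np.median(temp.crop(69, 70).samples)
        assert peak - before == pytest.approx(2.3, abs=0.3)
        # 30 s into the decay (tau = 120 s) about a quarter of the rise is gone
        assert end - before == pytest.approx(2.3 * np.exp(-30 / 120), abs=0.3)

    def test_heating_peaks_near_37(self):
        member = MemberParams(epoch_params=WALKING_EPOCH_PARAMS,
                              latency_targets={"before": 9.0, "active": 7.0, "after": 9.0})
        s = simulate_session(StimulusSpec(duration=5.0), member,
                             heating_protocol(before_s=10, active_s=10, after_s=10),
                             seed=2)
        assert float(np.max(s.channels["temperature"].samples)) == pytest.approx(37.0, abs=0.5)

    def test_motion_positive_only_while_walking(self, small_walking_cohort):
        s = small_walking_cohort[0]
        motion = s.channels["motion"]
        act = s.epoch("active")
        assert np.all(motion.crop(0, act.start - 0.1).samples == 0)
        assert np.median(motion.crop(act.start + 1, act.end - 1).samples) > 0.25

    def test_null_protocol_latency_stable(self):
        """Without a temperature change, before/active latencies agree to
        estimator noise (temperature-derived generation path)."""
        member = MemberParams(snr=4.0)
        s = simulate_session(StimulusSpec(duration=10.0), member,
                             null_protocol(before_s=15, active_s=15, after_s=15,
                                           temp_baseline=27.0), seed=3)
        lats = []
        for t0, t1 in ((10, 15), (25, 30)):
            c = cross_correlate(s.channels["stimulus"].crop(t0, t1),
                                s.channels["erg"].crop(t0, t1), 30.0)
            lats.append(xcorr_latency(c))
        assert abs(lats[0] - lats[1]) < 0.34  # one sample at 3 kHz

    def test_unknown_protocol_rejected(self):
        from dataclasses import replace
        proto = replace(walking_protocol(), kind="flying")
        with pytest.raises(InvalidArgumentError):
            simulate_session(StimulusSpec(duration=2.0), MemberParams(), proto, seed=0)

    def test_configured_delay_shift_round_trip(self):
        """Shifting the epoch latency target by d moves the measured
        cross-correlation latency by d, within one sample."""
        proto = null_protocol(before_s=12, active_s=1, after_s=1, temp_baseline=27.0)
        lats = {}
        for target in (7.0, 9.5):
            member = MemberParams(
                epoch_params={k: WALKING_EPOCH_PARAMS["before"] for k in
                              ("before", "active", "after")},
                latency_targets={k: target for k in ("before", "active", "after")},
                snr=0.0)
            s = simulate_session(StimulusSpec(duration=10.0), member, proto, seed=4)
            c = cross_correlate(s.channels["stimulus"].crop(2, 12),
                                s.channels["erg"].crop(2, 12), 30.0)
            lats[target] = xcorr_latency(c)
        assert lats[9.5] - lats[7.0] == pytest.approx(2.5, abs=1 / 3.0)
        # and the absolute latency matches the configured target
        assert lats[7.0] == pytest.approx(7.0, abs=1 / 3.0)


class TestCohorts:
    def test_cohort_bit_identical_for_same_spec(self):
        proto = walking_protocol(before_s=6, active_s=6, after_s=6)
        spec = CohortSpec(n_animals=2, protocol=proto, seed=9,
                          epoch_params=WALKING_EPOCH_PARAMS,
                          latency_medians={"before": 9.0, "active": 7.4, "after": 9.0})
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        for sa, sb in zip(a, b):
            for ch in sa.channels:
                np.testing.assert_array_equal(sa.channels[ch].samples,
                                              sb.channels[ch].samples)

    def test_zero_spread_makes_identical_animals(self):
        proto = walking_protocol(before_s=6, active_s=6, after_s=6)
        spec = CohortSpec(n_animals=3, protocol=proto, seed=9,
                          epoch_params=WALKING_EPOCH_PARAMS,
                          latency_medians={"before": 9.0, "active": 7.4, "after": 9.0},
                          latency_intercept_sd=0.0, temp_slope_sd=0.0,
                          temp_rise_sd=0.0, param_jitter=(0.0, 0.0, 0.0),
                          snr=0.0, artefact_rel_amp=0.0)
        sessions = simulate_cohort(spec)
        ref = sessions[0].channels["erg"].samples
        for s in sessions[1:]:
            np.testing.assert_array_equal(s.channels["erg"].samples, ref)


class TestAdaptation:
    def test_default_calibration_spans_1p4_ms(self):
        from ergpipe.stimulus import INTENSITY_SERIES
        diff = (adaptation_latency(INTENSITY_SERIES[0])
                - adaptation_latency(INTENSITY_SERIES[-1]))
        assert diff == pytest.approx(1.4, abs=1e-9)

    def test_single_intensity_is_constant(self):
        assert adaptation_latency(1.74e14) == pytest.approx(9.0, abs=1e-9)
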