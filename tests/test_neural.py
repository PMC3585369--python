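"""Neural mass model: kernels, sigmoid, drive, network dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import fsolve
from scipy.signal import periodogram

from tacsim.neural import (InstabilityError, NetworkConfig, NoiseSpec,
                           PopulationParams, StimulusSpec, SubpopulationParams,
                           TrapezoidDrive, alpha_population_params,
                           psp_impulse_response, sigmoid_rate, simulate_network,
                           simulate_trials, tcs_offset, trapezoid_drive)


def _peak_frequency(x, fs, lo=2.0, hi=20.0):
    f, p = periodogram(x, fs=fs, detrend="constant")
    sel = (f >= lo) & (f <= hi)
    return f[sel][np.argmax(p[sel])]


def _mean_abs_corr(S):
    C = np.corrcoef(S)
    iu = np.triu_indices_from(C, 1)
    return np.abs(C[iu]).mean()


class TestSigmoid:
    def test_midpoint_and_saturation(self):
        pop = alpha_population_params()
        assert sigmoid_rate(1.0, pop.P) == pytest.approx(10.0)       # v0_P = 1
        assert sigmoid_rate(4.0, pop.I) == pytest.approx(10.0)       # v0_I = 4
        assert sigmoid_rate(4.0, pop.Iprime) == pytest.approx(10.0)
        assert sigmoid_rate(1e3, pop.P) == pytest.approx(20.0)       # 2 e0
        assert sigmoid_rate(-1e3, pop.P) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(deadline=None, max_examples=50)
    def test_monotone_and_bounded(self, v1, v2):
        pop = alpha_population_params()
        s1, s2 = sigmoid_rate(v1, pop.P), sigmoid_rate(v2, pop.P)
        assert 0 < s1 < 20.0 and 0 < s2 < 20.0
        if v1 < v2:
            assert s1 <= s2
        if v2 - v1 > 1e-6:
            assert s1 < s2


class TestPSPKernel:
    def test_zero_at_origin(self):
        assert psp_impulse_response(0.0, 5.5, 40.0, 80.0) == 0.0

    def test_peak_time_closed_form(self):
        t = np.linspace(0, 0.2, 20001)
        h = psp_impulse_response(t, 5.5, 40.0, 80.0)
        t_star = np.log(80.0 / 40.0) / (80.0 - 40.0)   # = ln 2 / 40
        assert t[np.argmax(h)] == pytest.approx(t_star, abs=2e-5)
        assert t_star == pytest.approx(0.017329, abs=1e-6)

    def test_unit_dc_equal_rate_limit(self):
        """w2 -> w1 = a recovers gain a^2 t e^{-a t} under unit-DC."""
        a, gain = 100.0, 3.0
        t = np.linspace(1e-4, 0.1, 500)
        h = psp_impulse_response(t, gain, a, a * (1 + 1e-6), norm="unit_dc")
        ref = gain * a ** 2 * t * np.exp(-a * t)
        np.testing.assert_allclose(h, ref, rtol=1e-4)

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            psp_impulse_response(0.1, 5.5, 80.0, 40.0)

    def test_negative_time_is_zero(self):
        h = psp_impulse_response(np.array([-0.1, -1.0]), 5.5, 40.0, 80.0)
        np.testing.assert_array_equal(h, 0.0)


class TestTrapezoidDrive:
    def test_plateau_value(self):
        d = TrapezoidDrive(period=2.5, ramp_up=0.3, plateau=0.5, ramp_down=0.3,
                           amplitude=30.0)
        assert trapezoid_drive(0.3 + 0.25, d) == pytest.approx(30.0)

    @given(st.floats(0, 100))
    @settings(deadline=None, max_examples=50)
    def test_periodicity(self, t):
        d = TrapezoidDrive()
        assert trapezoid_drive(t, d) == pytest.approx(
            float(trapezoid_drive(t + d.period, d)), abs=1e-9)

    def test_zero_amplitude(self):
        d = TrapezoidDrive(amplitude=0.0)
        t = np.linspace(0, 5, 100)
        np.testing.assert_array_equal(trapezoid_drive(t, d), 0.0)

    def test_non_negative(self):
        d = TrapezoidDrive()
        t = np.linspace(0, 10, 1000)
        assert np.all(trapezoid_drive(t, d) >= 0)

    def test_invalid_segments(self):
        with pytest.raises(ValueError):
            TrapezoidDrive(period=1.0, ramp_up=0.5, plateau=0.5, ramp_down=0.5)


class TestTcsOffset:
    def test_modes(self):
        off = np.array([2.0, -1.0])
        none = StimulusSpec(mode="none")
        assert tcs_offset(0.5, none, 0) == 0.0
        dc = StimulusSpec(mode="dc", offsets=off)
        assert tcs_offset(123.0, dc, 0) == pytest.approx(2.0)
        sin = StimulusSpec(mode="sinusoid", frequency=10.0, offsets=off)
        assert tcs_offset(0.0, sin, 0) == pytest.approx(0.0)
        assert tcs_offset(1.0 / 40.0, sin, 1) == pytest.approx(-1.0)

    def test_region_bounds(self):
        sin = StimulusSpec(mode="sinusoid", frequency=10.0,
                           offsets=np.array([1.0]))
        with pytest.raises(IndexError):
            tcs_offset(0.0, sin, 5)

    def test_missing_offsets_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(mode="dc")


class TestSinglePopulation:
    def test_alpha_peak(self):
        """Isolated population with the default parameter set oscillates
        with a spectral peak inside the alpha band."""
        pop = alpha_population_params()
        net = NetworkConfig(n_cortical=1, subcortical_gain=0.0, duration=60.0)
        res = simulate_network(pop, net, StimulusSpec(), seed=0)
        assert 8.0 <= _peak_frequency(res.S[0], res.fs) <= 12.0

    def test_determinism(self):
        pop = alpha_population_params()
        net = NetworkConfig(n_cortical=1, subcortical_gain=0.0, duration=5.0)
        a = simulate_network(pop, net, StimulusSpec(), seed=42)
        b = simulate_network(pop, net, StimulusSpec(), seed=42)
        np.testing.assert_array_equal(a.S, b.S)
        np.testing.assert_array_equal(a.subcortical_trace, b.subcortical_trace)

    def test_batch_matches_single(self):
        pop = alpha_population_params()
        net = NetworkConfig(n_cortical=3, duration=5.0)
        batch = simulate_trials(pop, net, StimulusSpec(), seeds=[7, 8])
        single = simulate_network(pop, net, StimulusSpec(), seed=8)
        np.testing.assert_array_equal(batch[1].S, single.S)

    def test_dc_monotonicity(self):
        """Time-averaged pyramidal firing rate is non-decreasing in a DC
        membrane offset swept over [-2, +2] mV."""
        pop = alpha_population_params()
        net = NetworkConfig(n_cortical=1, subcortical_gain=0.0, duration=20.0)
        rates = []
        for dc in (-2.0, -1.0, 0.0, 1.0, 2.0):
            stim = (StimulusSpec(mode="dc", offsets=np.array([dc]))
                    if dc != 0 else StimulusSpec())
            res = simulate_network(pop, net, stim, seed=5)
            rates.append(sigmoid_rate(res.S[0] + dc, pop.P).mean())
        assert np.all(np.diff(rates) > 0)

    def test_dt_convergence(self):
        """Halving the integration step moves the alpha peak < 0.2 Hz."""
        pop = alpha_population_params()
        peaks = []
        for dt in (1 / 512, 1 / 1024):
            net = NetworkConfig(n_cortical=1, subcortical_gain=0.0,
                                duration=40.0, dt=dt)
            res = simulate_network(pop, net, StimulusSpec(), seed=0)
            peaks.append(_peak_frequency(res.S[0], res.fs))
        assert abs(peaks[0] - peaks[1]) < 0.2

    def test_noise_free_fixed_point_matches_algebra(self):
        """Without noise, drive or stimulus, a non-oscillating variant
        settles onto the algebraic stationary state (independent
        root-finding oracle on the stationary equations)."""
        base = alpha_population_params()
        # weaken recurrent excitation so the fixed point is stable
        from dataclasses import replace
        pop = replace(base, C=replace(base.C, C_PP=10.0))
        mean_rate = 60.0
        net = NetworkConfig(n_cortical=1, subcortical_gain=0.0, duration=20.0,
                            noise=NoiseSpec(mean=mean_rate, sd=0.0),
                            drive=TrapezoidDrive(amplitude=0.0))
        res = simulate_network(pop, net, StimulusSpec(), seed=0)
        tail = res.S[0][-512:]
        assert tail.std() < 1e-6, "network did not settle"

        # independent oracle: stationary filter outputs y = DC * input
        P, I, Ip, C = pop.P, pop.I, pop.Iprime, pop.C
        w_ref = pop.w_ref
        dc_e = P.gain / w_ref
        dc_i = I.gain / w_ref
        dc_s = Ip.gain / w_ref

        def stationary(y):
            ye, yi, ys = y
            yn = dc_e * mean_rate
            vp = C.C_PP * ye + yn - C.C_IP * yi - C.C_IsP * ys
            vi = C.C_PI * ye - C.C_II * yi - C.C_IsI * ys
            vis = C.C_PIs * ye - C.C_IsIs * ys
            return [ye - dc_e * sigmoid_rate(vp, P),
                    yi - dc_i * sigmoid_rate(vi, I),
                    ys - dc_s * sigmoid_rate(vis, Ip)]

        ye, yi, ys = fsolve(stationary, [0.1, 0.1, 0.1], xtol=1e-12)
        vp_ref = (C.C_PP * ye + dc_e * mean_rate - C.C_IP * yi - C.C_IsP * ys)
        assert tail[-1] == pytest.approx(vp_ref, abs=1e-6)

    def test_instability_reported(self):
        pop = alpha_population_params()
        unstable = PopulationParams(P=pop.P, I=pop.I, Iprime=pop.Iprime,
                                    C=pop.C, kernel_norm="unit_dc")
        net = NetworkConfig(n_cortical=1, subcortical_gain=0.0, duration=5.0,
                            noise=NoiseSpec(mean=150.0, sd=30.0))
        with pytest.raises(InstabilityError, match="dt"):
            simulate_network(unstable, net, StimulusSpec(), seed=0)


class TestNetwork:
    def test_uncoupled_populations_desynchronized(self):
        pop = alpha_population_params()
        net = NetworkConfig(n_cortical=5, subcortical_gain=0.0, duration=60.0)
        res = simulate_network(pop, net, StimulusSpec(), seed=0)
        assert _mean_abs_corr(res.S) < 0.2

    def test_subcortical_drive_synchronizes(self):
        pop = alpha_population_params()
        uncoupled = NetworkConfig(n_cortical=5, subcortical_gain=0.0,
                                  duration=60.0)
        coupled = NetworkConfig(n_cortical=5, duration=60.0)
        r0 = simulate_network(pop, uncoupled, StimulusSpec(), seed=0)
        r1 = simulate_network(pop, coupled, StimulusSpec(), seed=0)
        assert _mean_abs_corr(r1.S) >= _mean_abs_corr(r0.S) + 0.3

    def test_alpha_envelope_modulated_at_trapezoid_period(self):
        """The across-region mean alpha envelope is periodically
        modulated at the 2.5 s pacemaker drive period: the envelope
        spectrum has its 0.2-1.2 Hz maximum exactly at the 0.4 Hz
        drive rate, far above background."""
        from scipy.signal import butter, filtfilt, hilbert, periodogram

        pop = alpha_population_params()
        net = NetworkConfig(n_cortical=66, duration=60.0)
        res = simulate_network(pop, net, StimulusSpec(), seed=3)
        fs = res.fs
        b, a = butter(4, [8 / (fs / 2), 12 / (fs / 2)], btype="band")
        env = np.abs(hilbert(filtfilt(b, a, res.S, axis=1), axis=1)).mean(axis=0)
        f, p = periodogram(env - env.mean(), fs=fs, detrend="constant")
        sel = (f >= 0.2) & (f <= 1.2)
        drive_rate = 1.0 / net.drive.period
        assert f[sel][np.argmax(p[sel])] == pytest.approx(drive_rate, abs=0.05)
        line = p[np.argmin(np.abs(f - drive_rate))]
        background = np.median(p[sel & (np.abs(f - drive_rate) > 0.05)])
        assert line > 10 * background

    def test_sinusoidal_stimulus_entrains_peak(self):
        pop = alpha_population_params()
        net = NetworkConfig(n_cortical=2, subcortical_gain=0.0, duration=30.0)
        stim = StimulusSpec(mode="sinusoid", frequency=10.0,
                            offsets=np.array([1.0, 0.0]))
        res = simulate_network(pop, net, stim, seed=1)
        assert _peak_frequency(res.S[0], res.fs) == pytest.approx(10.0, abs=0.05)

    def test_offsets_length_checked(self):
        pop = alpha_population_params()
        net = NetworkConfig(n_cortical=3, duration=3.0)
        stim = StimulusSpec(mode="dc", offsets=np.array([1.0]))
        with pytest.raises(ValueError):
            simulate_network(pop, net, stim, seed=0)
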