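"""Photocurrent/current-clamp metrics against closed-form constructions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from narkit import (
    action_spectrum_peak,
    iv_fit,
    photocurrent_metrics,
    pulse_adaptation,
    saturation_fit,
    silencing_compare,
    simulate_photocurrent,
    spike_metrics,
)
from narkit.synth import PhotocurrentTrace


class TestPhotocurrentMetrics:
    def test_rectangular_pulse_has_unity_inactivation_ratio(self):
        tr = simulate_photocurrent(20, 20, 5, 10, [(100, 400)], duration_ms=500)
        m = photocurrent_metrics(tr)
        assert m.i_peak == pytest.approx(20.0, rel=1e-6)
        assert m.i_ss == pytest.approx(20.0, rel=1e-6)
        assert m.inactivation_ratio == pytest.approx(1.0, rel=1e-6)

    def test_peak_forty_steady_ten_gives_quarter_ratio(self):
        tr = simulate_photocurrent(40, 10, 15, 10, [(100, 400)], duration_ms=500)
        m = photocurrent_metrics(tr)
        assert m.i_peak == pytest.approx(40.0, rel=1e-3)
        assert m.inactivation_ratio == pytest.approx(0.25, rel=1e-2)

    def test_tau_off_recovered_within_five_percent_at_one_percent_noise(self):
        tr = simulate_photocurrent(
            40, 10, 20, 10.0, [(100, 400)], duration_ms=600, noise_sd=0.4, seed=42
        )
        m = photocurrent_metrics(tr)
        assert m.tau_off == pytest.approx(10.0, rel=0.05)

    def test_metrics_invariant_to_constant_baseline(self):
        tr = simulate_photocurrent(40, 10, 20, 10, [(100, 400)], duration_ms=500)
        shifted = PhotocurrentTrace(tr.time, tr.current + 37.0, tr.light_epochs)
        m0, m1 = photocurrent_metrics(tr), photocurrent_metrics(shifted)
        assert m1.i_peak == pytest.approx(m0.i_peak, rel=1e-9)
        assert m1.i_ss == pytest.approx(m0.i_ss, rel=1e-9)

    def test_no_light_epoch_rejected(self):
        tr = simulate_photocurrent(20, 10, 5, 10, [])
        with pytest.raises(ValueError, match="no light epoch"):
            photocurrent_metrics(tr)


class TestIVFit:
    def test_exact_line_recovered(self):
        v = np.array([-60.0, -40, -20, 0, 20, 40])
        iv = iv_fit(v, 0.5 * v + 30)
        assert iv.slope == pytest.approx(0.5)
        assert iv.intercept == pytest.approx(30.0)
        assert iv.r_squared == pytest.approx(1.0)
        assert not iv.voltage_insensitive

    def test_flat_relation_flagged_voltage_insensitive(self):
        v = np.arange(-70.0, 51, 10)
        rng = np.random.default_rng(0)
        iv = iv_fit(v, 20 + rng.normal(0, 0.2, v.size))
        assert iv.voltage_insensitive

    def test_noisy_slope_within_three_standard_errors(self):
        v = np.arange(-60.0, 41, 10)
        rng = np.random.default_rng(3)
        iv = iv_fit(v, 0.3 * v + 10 + rng.normal(0, 1.0, v.size))
        assert abs(iv.slope - 0.3) < 3 * iv.slope_stderr

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(st.floats(-80, 80), min_size=4, max_size=10, unique=True),
        st.floats(-1, 1),
        st.floats(-50, 50),
    )
    def test_matches_closed_form_ols(self, v, slope, intercept):
        """OLS oracle: slope = cov(v,i)/var(v) on arbitrary exact inputs."""
        v = np.array(sorted(v))
        i = slope * v + intercept
        iv = iv_fit(v, i)
        denom = np.sum((v - v.mean()) ** 2)
        expected = np.sum((v - v.mean()) * (i - i.mean())) / denom
        assert iv.slope == pytest.approx(expected, abs=1e-9)


class TestActionSpectrum:
    @pytest.mark.parametrize("center", [520.0, 550.0])
    def test_gaussian_peak_found_within_half_grid_step(self, center):
        wl = np.arange(400.0, 651, 10)
        cur = np.exp(-0.5 * ((wl - center) / 40.0) ** 2)
        asp = action_spectrum_peak(wl, cur)
        assert asp.peak_nm == pytest.approx(center, abs=5.0)
        assert asp.normalized_current.max() == pytest.approx(1.0)

    def test_edge_maximum_warns(self):
        wl = np.arange(400.0, 651, 10)
        with pytest.warns(UserWarning, match="edge"):
            asp = action_spectrum_peak(wl, wl / wl.max())
        assert asp.edge_peak
        assert asp.peak_nm == 650.0


class TestSaturation:
    def test_exact_hyperbola_inverted(self):
        p = np.array([0.05, 0.1, 0.2, 0.4, 0.8, 1.6])
        i_max, p_half = saturation_fit(p, 30 * p / (p + 0.2))
        assert i_max == pytest.approx(30.0, rel=1e-3)
        assert p_half == pytest.approx(0.2, rel=1e-3)
        # identity: current at P = p_half is half-maximal
        assert 30 * p_half / (p_half + 0.2) == pytest.approx(i_max / 2, rel=1e-3)

    def test_five_percent_noise_recovered_within_ten_percent(self):
        """Typical (median over fixed seeds) recovery error stays below 10%
        under 5% signal-proportional noise on a 10-point log protocol."""
        p = np.geomspace(0.025, 3.2, 10)
        clean = 30 * p / (p + 0.2)
        errs = []
        for seed in range(9):
            rng = np.random.default_rng(seed)
            i_max, p_half = saturation_fit(p, clean * (1 + rng.normal(0, 0.05, p.size)))
            errs.append(max(abs(i_max - 30) / 30, abs(p_half - 0.2) / 0.2))
        assert np.median(errs) < 0.10


class TestPulseAdaptation:
    def _train(self, peaks, period=50.0, width=3.0):
        t = np.arange(0.0, period * len(peaks) + 20, 0.1)
        i = np.zeros_like(t)
        onsets = [20.0 + k * period for k in range(len(peaks))]
        for on, pk in zip(onsets, peaks):
            i[(t >= on) & (t < on + width)] = pk
        return PhotocurrentTrace(t, i, tuple((on, on + width) for on in onsets)), onsets

    def test_identical_pulses_give_unit_ratio(self):
        tr, onsets = self._train([20.0] * 6)
        peaks, ratio = pulse_adaptation(tr, onsets)
        assert ratio == pytest.approx(1.0)

    def test_geometric_decay_ratio(self):
        tr, onsets = self._train([20 * 0.9**k for k in range(6)])
        _, ratio = pulse_adaptation(tr, onsets)
        assert ratio == pytest.approx(0.9**5, rel=1e-9)

    def test_pulses_below_resolution_rejected(self):
        tr, _ = self._train([20.0, 20.0])
        with pytest.raises(ValueError, match="closer than"):
            pulse_adaptation(tr, [20.0, 20.05])


class TestSpikes:
    def _spiky_trace(self, spike_times, duration=500.0, dt=0.1, v_rest=-65.0):
        t = np.arange(0.0, duration, dt)
        v = np.full_like(t, v_rest)
        for st_ in spike_times:
            v[(t >= st_) & (t < st_ + 1.0)] = 20.0
        return t, v

    def test_counts_injected_spikes(self):
        times = [50, 120, 190, 260, 330]
        t, v = self._spiky_trace(times)
        m = spike_metrics(t, v)
        assert m.n_spikes == 5
        assert m.latency_first_spike == pytest.approx(50.0, abs=0.2)

    def test_identical_traces_give_zero_shift(self):
        t, v = self._spiky_trace([100, 200])
        a, b = spike_metrics(t, v), spike_metrics(t, v)
        T, dn = silencing_compare(a, b)
        assert T == 0.0 and dn == 0

    def test_delayed_first_spike_measured_as_latency_shift(self):
        t, v_unlit = self._spiky_trace([100, 200, 300])
        _, v_lit = self._spiky_trace([220, 320])
        T, dn = silencing_compare(spike_metrics(t, v_lit), spike_metrics(t, v_unlit))
        assert T == pytest.approx(120.0, abs=0.2)
        assert dn == -1

    def test_count_invariant_to_suprathreshold_scaling(self):
        t, v = self._spiky_trace([100, 200])
        m1 = spike_metrics(t, v)
        m2 = spike_metrics(t, np.where(v > -20, v * 2, v))
        assert m1.n_spikes == m2.n_spikes
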