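import numpy as np
import pytest

from habpipe import synthetic_data as sd
from habpipe.behavior_locomotion import cue_window_speed, speed_from_positions


class TestTransientKernel:
    def test_peak_position_and_height(self):
        """Kernel peaks exactly at t_peak with unit height, for every preset."""
        t = np.arange(0, 40, 0.002)
        for preset in sd.TRANSIENT_PRESETS.values():
            k = sd.transient_kernel(t, preset.t_peak, preset.tau_decay)
            assert t[np.argmax(k)] == pytest.approx(preset.t_peak, abs=0.002)
            assert k.max() == pytest.approx(1.0, abs=1e-9)
            assert np.all(k[t < 0] == 0) if np.any(t < 0) else True

    def test_rise_tau_reproduces_peak_time(self):
        for t_peak, tau_d in [(0.68, 5.88), (0.26, 1.89), (0.05, 10.0)]:
            tau_r = sd.solve_rise_tau(t_peak, tau_d)
            assert 0 < tau_r < tau_d
            tp = np.log(tau_d / tau_r) * tau_d * tau_r / (tau_d - tau_r)
            assert tp == pytest.approx(t_peak, rel=1e-9)

    def test_invalid_peak_time_rejected(self):
        with pytest.raises(ValueError):
            sd.solve_rise_tau(6.0, 5.88)


class TestPhotometrySession:
    def test_zero_amplitude_zero_noise_is_pure_drift(self):
        preset = sd.TransientPreset(0.0, 0.68, 5.88, amplitude_cv=0.0, noise_sd=0.0, drift_tau=500.0)
        rec, _ = sd.gen_photometry_session(preset, 2, sd.LAYOUTS["footshock"], seed=0)
        np.testing.assert_allclose(rec.trace, np.exp(-rec.times / 500.0), rtol=1e-12)

    def test_fixed_seed_byte_identical(self):
        a = sd.gen_photometry_session(sd.TRANSIENT_PRESETS["quinine"], 3, sd.LAYOUTS["quinine"], seed=5)
        b = sd.gen_photometry_session(sd.TRANSIENT_PRESETS["quinine"], 3, sd.LAYOUTS["quinine"], seed=5)
        assert a[0].trace.tobytes() == b[0].trace.tobytes()
        assert np.array_equal(a[1].onsets, b[1].onsets)

    def test_learning_schedule_scales_cue_response(self):
        """Early-trial cue transients are tiny, late-trial ones near asymptote."""
        preset = sd.TransientPreset(0.3, 0.68, 5.88, amplitude_cv=0.0, noise_sd=0.0, drift_tau=np.inf)
        rec, ev = sd.gen_photometry_session(
            preset, 20, sd.LAYOUTS["conditioning_footshock"],
            schedule=sd.AVERSIVE_SCHEDULE, seed=2,
        )
        cues = ev.select("cue").onsets
        i_first = int(round((cues[0] + 0.68) * rec.rate))
        i_last = int(round((cues[-1] + 0.68) * rec.rate))
        assert rec.trace[i_first] - 1.0 < 0.01
        assert rec.trace[i_last] - 1.0 > 0.25

    def test_rejects_bad_trial_count(self):
        with pytest.raises(ValueError):
            sd.gen_photometry_session(sd.TRANSIENT_PRESETS["quinine"], 0, sd.LAYOUTS["quinine"], seed=0)


class TestLearningSchedule:
    def test_logistic_shape(self):
        for sched in (sd.AVERSIVE_SCHEDULE, sd.APPETITIVE_SCHEDULE):
            g = sched.gain(np.arange(1, 1001))
            assert g[0] < 0.02
            assert np.all(np.diff(g) >= 0)  # monotone (flat only once saturated)
            assert np.all(np.diff(g[: int(2 * sched.h)]) > 0)
            assert g[-1] > 0.99


class TestSpikeUnit:
    def test_zero_rate_zero_spikes(self):
        preset = sd.SpikeProfilePreset(0.0, 0.0, 0.0, 0.0, 1.0, "type1")
        unit, _ = sd.gen_spike_unit(preset, 2, sd.LAYOUTS["conditioning_sucrose"], seed=0)
        assert unit.n_spikes == 0

    def test_homogeneous_poisson_count(self):
        """Constant 30 spikes/s: count within 4 sigma of rate x duration."""
        preset = sd.SpikeProfilePreset(30.0, 30.0, 30.0, 30.0, 1.0, "type1")
        unit, _ = sd.gen_spike_unit(preset, 3, sd.LAYOUTS["conditioning_sucrose"], seed=12)
        expected = 30.0 * unit.t_stop
        assert abs(unit.n_spikes - expected) < 4.0 * np.sqrt(expected)

    def test_type1_rate_function_never_exceeds_baseline(self):
        """Pure-inhibition profiles stay at or below baseline after the US."""
        preset = sd.SPIKE_PRESETS["sucrose_type1"]
        t = np.arange(-2, 10, 0.01)
        r = sd.spike_rate_function(t + 100.0, np.array([100.0]), preset)
        assert np.all(r <= preset.baseline_rate + 1e-12)

    def test_type2_rate_rebounds_above_baseline(self):
        preset = sd.SPIKE_PRESETS["sucrose_type2"]
        r = sd.spike_rate_function(np.array([105.1]), np.array([100.0]), preset)
        assert r[0] > preset.baseline_rate

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sd.SpikeProfilePreset(baseline_rate=-1.0)


class TestTagging:
    def test_reliability_one_jitter_zero_exact_latency(self):
        preset = sd.TaggingPreset(latency_mean=0.004, latency_jitter=0.0, reliability=1.0,
                                  spont_rate=0.0, n_pulses=50)
        unit = sd.gen_tagging_epoch(preset, seed=0)
        lat = unit.spike_times - unit.light_pulses[np.searchsorted(unit.light_pulses, unit.spike_times) - 1]
        np.testing.assert_allclose(lat, 0.004, atol=1e-12)
        assert unit.n_spikes == 50

    def test_reliability_zero_pure_poisson_rate(self):
        preset = sd.TaggingPreset(reliability=0.0, spont_rate=20.0, n_pulses=100)
        unit = sd.gen_tagging_epoch(preset, seed=1)
        expected = 20.0 * unit.t_stop
        assert abs(unit.n_spikes - expected) < 4.0 * np.sqrt(expected)

    def test_reliability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sd.TaggingPreset(reliability=1.2)


class TestPopulation:
    def test_counts_and_shared_schedule(self):
        spec = sd.MixtureSpec({"sucrose_type1": 1, "sucrose_type2": 1}, n_trials=3, seed=0)
        units, ev, names = sd.gen_population(spec)
        assert len(units) == 2 and sorted(names) == ["sucrose_type1", "sucrose_type2"]

    def test_per_unit_seeds_keyed_by_index(self):
        """Regenerating the same spec yields byte-identical per-unit data."""
        spec = sd.MixtureSpec({"sucrose_type1": 2, "sucrose_type2": 1}, n_trials=3, seed=9)
        a, _, _ = sd.gen_population(spec)
        b, _, _ = sd.gen_population(
            sd.MixtureSpec({"sucrose_type2": 1, "sucrose_type1": 2}, n_trials=3, seed=9)
        )
        for ua, ub in zip(a, b):
            assert ua.spike_times.tobytes() == ub.spike_times.tobytes()

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            sd.MixtureSpec({"sucrose_type1": 1}, seed=0)


class TestLocomotion:
    def test_no_suppression_stationary_speed(self):
        """With no schedule, cue-window speed has no systematic trend."""
        ev, _ = sd.gen_trial_events(sd.LAYOUTS["conditioning_footshock"], 20, np.random.default_rng(0))
        pos = sd.gen_locomotion(ev, None, seed=4)
        blocks = cue_window_speed(speed_from_positions(pos), ev, label="cue", block=5)
        assert blocks.size == 4
        assert np.ptp(blocks) < 0.5 * blocks.mean()

    def test_suppression_reduces_late_blocks(self):
        ev, _ = sd.gen_trial_events(sd.LAYOUTS["conditioning_footshock"], 20, np.random.default_rng(0))
        pos = sd.gen_locomotion(ev, sd.AVERSIVE_SCHEDULE, seed=4)
        blocks = cue_window_speed(speed_from_positions(pos), ev, label="cue", block=5)
        assert blocks[-1] < 0.5 * blocks[0]

    def test_seed_reproducible(self):
        ev, _ = sd.gen_trial_events(sd.LAYOUTS["footshock"], 3, np.random.default_rng(1))
        a = sd.gen_locomotion(ev, seed=2)
        b = sd.gen_locomotion(ev, seed=2)
        assert a.xy.tobytes() == b.xy.tobytes()
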