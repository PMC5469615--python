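import numpy as np
import pytest

from habpipe import synthetic_data as sd
from habpipe.optotag import (
    evoked_latency_reliability,
    tag_unit,
    tagging_pvalue,
    waveform_correlation,
)
from habpipe.session_io import SpikeUnit


def _locked_unit(seed=3, **kw):
    return sd.gen_tagging_epoch(sd.TaggingPreset(**kw), seed=seed)


class TestWaveformCorrelation:
    def test_identical_is_one(self):
        wf = np.random.default_rng(0).standard_normal((4, 32))
        assert waveform_correlation(wf, wf) == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        wf = np.random.default_rng(0).standard_normal((4, 32))
        assert waveform_correlation(wf, -wf) == pytest.approx(-1.0)

    def test_constant_waveform_undefined(self):
        assert np.isnan(waveform_correlation(np.ones((1, 8)), np.arange(8.0)[None]))

    def test_synthetic_perturbed_waveform_passes_threshold(self):
        """5% perturbation of the spontaneous waveform keeps C above 0.85."""
        u = _locked_unit()
        assert waveform_correlation(u.waveform_mean, u.waveform_evoked) > 0.85


class TestLatencyReliability:
    def test_perfectly_locked_unit(self):
        u = _locked_unit(latency_mean=0.004, latency_jitter=0.0, reliability=1.0, spont_rate=0.0,
                         n_pulses=40)
        lat, r = evoked_latency_reliability(u)
        assert r == 1.0
        np.testing.assert_allclose(lat, 0.004, atol=1e-12)

    def test_empty_spike_train_zero_reliability(self):
        u = SpikeUnit([], np.ones((1, 8)), light_pulses=np.arange(10) * 0.1, t_start=0.0, t_stop=50.0)
        lat, r = evoked_latency_reliability(u)
        assert r == 0.0 and lat.size == 0

    def test_reliability_recovered_within_binomial_ci(self):
        """600 pulses at preset reliability 0.9 over 30 Hz spontaneous firing.

        A window hit occurs for an evoked spike OR a chance spontaneous
        spike, so the expected hit rate is R + (1-R)(1 - exp(-lambda w)).
        """
        preset = sd.TaggingPreset(reliability=0.9, spont_rate=30.0, n_pulses=600)
        u = _locked_unit(seed=5, reliability=0.9, spont_rate=30.0, n_pulses=600)
        _, r = evoked_latency_reliability(u)
        expected = 0.9 + 0.1 * (1.0 - np.exp(-preset.spont_rate * 0.010))
        se = np.sqrt(expected * (1 - expected) / 600)
        assert abs(r - expected) < 4 * se

    def test_no_pulses_rejected(self):
        with pytest.raises(ValueError):
            evoked_latency_reliability(SpikeUnit([1.0], np.ones((1, 8))))


class TestTaggingPvalue:
    def test_locked_unit_reaches_floor(self):
        u = _locked_unit(n_pulses=200)
        p = tagging_pvalue(u, n_boot=200, seed=0)
        assert p == pytest.approx(1.0 / 201.0)

    def test_shift_invariance_and_determinism(self):
        u = _locked_unit(n_pulses=100)
        shifted = SpikeUnit(
            u.spike_times + 123.0,
            u.waveform_mean,
            light_pulses=u.light_pulses + 123.0,
            pulse_width=u.pulse_width,
            t_start=u.t_start + 123.0,
            t_stop=u.t_stop + 123.0,
        )
        p1 = tagging_pvalue(u, n_boot=100, seed=4)
        p2 = tagging_pvalue(shifted, n_boot=100, seed=4)
        assert p1 == p2

    def test_silent_pulse_windows_not_tagged(self):
        """A unit with no spikes near any pulse gets a large p."""
        rng = np.random.default_rng(0)
        pulses = 700.0 + np.arange(50) / 10.0
        spikes = np.sort(rng.uniform(0, 690.0, 2000))
        u = SpikeUnit(spikes, np.ones((1, 8)), light_pulses=pulses, t_start=0.0, t_stop=710.0)
        p = tagging_pvalue(u, n_boot=100, seed=0)
        assert p > 0.5

    def test_median_latency_variant_agrees_on_locked_unit(self):
        u = _locked_unit(n_pulses=200)
        p = tagging_pvalue(u, n_boot=200, seed=0, statistic="median_latency")
        assert p == pytest.approx(1.0 / 201.0)

    def test_insufficient_spontaneous_epoch_rejected(self):
        u = SpikeUnit(
            np.arange(0.0, 60.0, 0.5) + 0.01,
            np.ones((1, 8)),
            light_pulses=np.arange(5.0, 55.0, 0.1),
            t_start=0.0,
            t_stop=60.0,
        )
        with pytest.raises(ValueError, match="stimulation-free"):
            tagging_pvalue(u, n_boot=10, seed=0)


class TestTagDecision:
    def test_locked_unit_tagged(self):
        res = tag_unit(_locked_unit(), n_boot=1000, seed=3)
        assert res.tagged and res.c > 0.85 and res.p < 0.001

    def test_unmodulated_unit_not_tagged(self):
        res = tag_unit(_locked_unit(seed=11, reliability=0.0), n_boot=200, seed=11)
        assert not res.tagged and res.p >= 0.005

    def test_threshold_is_strict(self):
        """p exactly at 1/(n_boot+1) with n_boot=999 equals 0.001: not tagged."""
        res = tag_unit(_locked_unit(), n_boot=999, seed=3)
        assert res.p == pytest.approx(0.001)
        assert not res.tagged
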