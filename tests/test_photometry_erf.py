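import numpy as np
import pytest

from habpipe.photometry_erf import (
    ERFMatrix,
    block_average,
    compute_dff,
    erf_summary,
    learning_onset,
    response_metrics,
    smooth_trace,
    zscore_erf,
)
from habpipe.session_io import EventStream, Recording


def _rec(trace, rate=500.0):
    return Recording(np.asarray(trace, dtype=float), rate)


class TestSmoothTrace:
    def test_constant_unchanged(self):
        rec = _rec(np.full(100, 3.3))
        np.testing.assert_allclose(smooth_trace(rec).trace, rec.trace, rtol=1e-12)

    def test_impulse_spreads_to_span(self):
        """A unit impulse under a 10-sample average becomes 10 samples of 0.1."""
        x = np.zeros(100)
        x[50] = 1.0
        out = smooth_trace(_rec(x), span=0.020).trace
        assert np.count_nonzero(out) == 10
        np.testing.assert_allclose(out[out > 0], 0.1)

    def test_mean_preserved(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        out = smooth_trace(_rec(x)).trace
        # linear filter with shrunken edge windows: interior mass preserved
        assert out.mean() == pytest.approx(x.mean(), abs=5e-3)
        assert out.size == x.size

    def test_span_errors(self):
        with pytest.raises(ValueError):
            smooth_trace(_rec(np.ones(5)), span=1.0)
        with pytest.raises(ValueError):
            smooth_trace(_rec(np.ones(500)), span=1e-9)


class TestComputeDff:
    def _events(self, onsets):
        return EventStream(onsets, ["us"] * len(onsets), [0.5] * len(onsets))

    def test_constant_trace_gives_zero(self):
        rec = _rec(np.full(5000, 2.0))
        m = compute_dff(rec, self._events([5.0]), (-2, -0.5), (-2, 2))
        np.testing.assert_allclose(m.values, 0.0)

    def test_doubled_fluorescence_gives_one(self):
        x = np.full(5000, 1.0)
        x[2500:3000] = 2.0
        m = compute_dff(_rec(x), self._events([5.0]), (-2, -0.5), (-2, 2))
        assert m.values[0, m.window_slice((0.1, 0.9))].mean() == pytest.approx(1.0)

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(3)
        x = 2.0 + 0.1 * rng.standard_normal(6000)
        ev = self._events([4.0, 8.0])
        m1 = compute_dff(_rec(x), ev, (-2, -0.5), (-2, 2))
        m2 = compute_dff(_rec(7.3 * x), ev, (-2, -0.5), (-2, 2))
        np.testing.assert_allclose(m1.values, m2.values, rtol=1e-12)

    def test_invariant_to_common_time_shift(self):
        rng = np.random.default_rng(3)
        x = 2.0 + 0.1 * rng.standard_normal(6000)
        shift = 512
        ev = self._events([4.0])
        ev2 = self._events([4.0 + shift / 500.0])
        x2 = np.concatenate([np.ones(shift), x])
        m1 = compute_dff(_rec(x), ev, (-2, -0.5), (-2, 2))
        m2 = compute_dff(_rec(x2), ev2, (-2, -0.5), (-2, 2))
        np.testing.assert_allclose(m1.values, m2.values, rtol=1e-12)

    def test_nonpositive_baseline_excluded(self, caplog):
        x = np.full(5000, 1.0)
        x[1000:2000] = -1.0  # poisons the first event's baseline
        ev = self._events([5.0, 8.0])
        m = compute_dff(_rec(x), ev, (-2, -0.5), (-2, 2))
        assert m.n_trials == 1 and m.trial_order.tolist() == [1]
        with pytest.raises(ValueError, match="all trials excluded"):
            compute_dff(_rec(np.full(5000, -1.0)), self._events([5.0]), (-2, -0.5), (-2, 2))


class TestSummaryAndMetrics:
    def test_single_trial_sem_zero_flagged(self):
        m = ERFMatrix(np.ones((1, 10)), np.arange(10) * 0.002)
        s = erf_summary(m)
        assert s.single_trial and np.all(s.sem == 0)

    def test_identical_trials_sem_zero(self):
        m = ERFMatrix(np.ones((2, 10)), np.arange(10) * 0.002)
        assert np.all(erf_summary(m).sem == 0)

    def test_pure_exponential_tau_recovered_exactly(self):
        t = np.arange(0, 10, 0.002)
        m = ERFMatrix((0.3 * np.exp(-t / 2.5))[None, :], t)
        met = response_metrics(m, (0.0, 10.0))
        assert met.tau_decay == pytest.approx(2.5, rel=1e-6)
        assert met.peak_dff == pytest.approx(0.3)
        assert not met.tau_flagged

    def test_flat_zero_flagged(self):
        m = ERFMatrix(np.zeros((2, 100)), np.arange(100) * 0.002)
        met = response_metrics(m, (0.0, 0.2))
        assert met.peak_dff == 0.0 and np.isnan(met.tau_decay) and met.tau_flagged

    def test_noiseless_quinine_kernel_metrics(self, noiseless_quinine):
        """Generator + pipeline round trip: preset (27.8%, 0.68 s, 5.88 s) recovered."""
        preset, rec, ev = noiseless_quinine
        m = compute_dff(smooth_trace(rec), ev, (-2, -0.5), (-2, 10))
        met = response_metrics(m, (0.0, 10.0))
        assert met.peak_dff == pytest.approx(0.278, rel=0.005)
        assert met.t_peak == pytest.approx(0.68, abs=0.01)
        assert met.tau_decay == pytest.approx(5.88, rel=0.01)

    def test_auc_additive_over_partition(self, noiseless_quinine):
        _, rec, ev = noiseless_quinine
        m = compute_dff(smooth_trace(rec), ev, (-2, -0.5), (-2, 10))
        whole = response_metrics(m, (0.0, 10.0)).auc
        parts = sum(response_metrics(m, w).auc for w in [(0.0, 2.0), (2.0, 4.5), (4.5, 10.0)])
        assert whole == pytest.approx(parts, rel=1e-9)


class TestZscoreErf:
    def test_control_window_standardized(self):
        rng = np.random.default_rng(0)
        t = np.arange(-2, 10, 0.002)
        m = ERFMatrix(rng.standard_normal((8, t.size)), t)
        z = zscore_erf(m, (-2, -0.5))
        sl = m.window_slice((-2, -0.5))
        assert z[sl].mean() == pytest.approx(0.0, abs=1e-9)
        assert z[sl].std(ddof=1) == pytest.approx(1.0, rel=1e-9)


class TestBlocksAndOnset:
    @pytest.mark.parametrize(
        "n, block, expected",
        [(20, 5, 4), (30, 5, 6), (7, 1, 7), (7, 3, 3)],
    )
    def test_block_counts(self, n, block, expected):
        assert block_average(np.arange(n, dtype=float), block).size == expected

    def test_block_values(self):
        out = block_average(np.array([1.0, 3.0, 5.0, 7.0, 10.0]), 2)
        np.testing.assert_allclose(out, [2.0, 6.0, 10.0])  # trailing partial block

    def test_constant_blocks_constant(self):
        np.testing.assert_allclose(block_average(np.full(12, 4.2), 5), 4.2)

    @pytest.mark.parametrize(
        "flags, expected",
        [
            ([True, True, True], 1),
            ([False, False, False], None),
            ([False, False, True, True], 3),
            ([True, False, True, True], 3),
            ([True, True, False], None),
        ],
    )
    def test_learning_onset(self, flags, expected):
        assert learning_onset(flags) == expected

    def test_learning_onset_needs_two_blocks(self):
        with pytest.raises(ValueError):
            learning_onset([True])
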