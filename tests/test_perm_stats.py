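import itertools

import numpy as np
import pytest

from habpipe.perm_stats import ks_compare, maxt_test, strength_perm_test
from habpipe.photometry_erf import ERFMatrix


def _erf(data, dt=0.05, t0=0.0):
    data = np.atleast_2d(data)
    return ERFMatrix(data, t0 + np.arange(data.shape[1]) * dt)


def _brute_force_maxt(data, baseline_slice):
    """Independent oracle: exact sign-flip enumeration of the max-|T| null."""
    c = data - data[:, baseline_slice].mean(axis=1, keepdims=True)
    n = c.shape[0]

    def tstat(x):
        sd = x.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = x.mean(axis=0) / (sd / np.sqrt(n))
        return np.where(sd > 0, t, 0.0)

    t_obs = tstat(c)
    maxs = [
        np.abs(tstat(np.asarray(s)[:, None] * c)).max()
        for s in itertools.product([1.0, -1.0], repeat=n)
    ]
    p = np.array([np.mean([mx >= abs(t) - 1e-12 for mx in maxs]) for t in t_obs])
    return t_obs, p


class TestMaxT:
    def test_all_zero_data_no_segments(self):
        m = _erf(np.zeros((4, 30)))
        res = maxt_test(m, (0.0, 0.25), n_perm=200, seed=0)
        assert res.segments_up == [] and res.segments_down == []
        assert np.all(res.p == 1.0)

    def test_exhaustive_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        data = rng.standard_normal((4, 25))
        m = _erf(data)
        res = maxt_test(m, (0.0, 0.25), exhaustive=True)
        t_bf, p_bf = _brute_force_maxt(data, slice(0, 5))
        np.testing.assert_allclose(res.t_obs, t_bf, rtol=1e-10)
        np.testing.assert_allclose(res.p, p_bf, atol=1e-12)
        assert res.n_perm == 16

    def test_exhaustive_invariant_to_trial_order(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((5, 20))
        m1 = maxt_test(_erf(data), (0.0, 0.25), exhaustive=True)
        m2 = maxt_test(_erf(data[::-1]), (0.0, 0.25), exhaustive=True)
        np.testing.assert_allclose(m1.p, m2.p, atol=1e-12)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((8, 40))
        a = maxt_test(_erf(data), (0.0, 0.25), n_perm=300, seed=7)
        b = maxt_test(_erf(data), (0.0, 0.25), n_perm=300, seed=7)
        np.testing.assert_array_equal(a.p, b.p)

    def test_strong_response_detected_with_correct_sign(self):
        """An injected positive bump yields an up-segment covering it."""
        rng = np.random.default_rng(3)
        data = 0.05 * rng.standard_normal((10, 100))
        data[:, 40:60] += 1.0
        data[:, 70:80] -= 1.0
        m = _erf(data, dt=0.05, t0=-1.0)
        res = maxt_test(m, (-1.0, -0.5), n_perm=1000, seed=0)
        assert any(s <= 1.25 and e >= 1.75 for s, e in res.segments_up)
        assert any(s <= 2.55 and e >= 2.9 for s, e in res.segments_down)

    def test_family_wise_error_controlled_on_null(self):
        """Null Gaussian data: fraction of runs with any segment stays near alpha."""
        rng = np.random.default_rng(4)
        hits = 0
        n_runs = 100
        for i in range(n_runs):
            data = rng.standard_normal((8, 60))
            res = maxt_test(_erf(data), (0.0, 0.5), n_perm=300, seed=i)
            hits += bool(res.segments_up or res.segments_down)
        # binomial 99% upper bound around alpha = 0.05
        assert hits / n_runs <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / n_runs)

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            maxt_test(_erf(np.ones((1, 10))), (0.0, 0.25))

    def test_low_nperm_warns(self):
        with pytest.warns(UserWarning, match="n_perm"):
            maxt_test(_erf(np.random.default_rng(0).standard_normal((3, 10))), (0.0, 0.25), n_perm=50)


class TestStrengthPerm:
    def test_identical_groups_p_one(self):
        assert strength_perm_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_matches_exhaustive_enumeration_3v3(self):
        a = [0.1, 0.5, 0.9]
        b = [0.2, 0.6, 1.4]
        p = strength_perm_test(a, b)  # auto-exhaustive: C(6,3)=20 splits
        pooled = np.array(a + b)
        d_obs = abs(np.mean(a) - np.mean(b))
        count = sum(
            abs(pooled[list(pick)].mean() - np.delete(pooled, pick).mean()) >= d_obs - 1e-12
            for pick in itertools.combinations(range(6), 3)
        )
        assert p == pytest.approx(count / 20.0)

    def test_separated_groups_min_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.01, 12)
        b = rng.normal(10.0, 0.01, 12)
        p = strength_perm_test(a, b, n_perm=999, seed=1, exhaustive=False)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            strength_perm_test([1.0], [1.0, 2.0])


class TestKS:
    def test_identical_samples_d_zero(self):
        x = [0.1, 0.4, 0.9, 1.3]
        d, p = ks_compare(x, x)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports_d_one(self):
        d, _ = ks_compare([0.0, 1.0, 2.0], [10.0, 11.0, 12.0])
        assert d == 1.0

    def test_matches_brute_force_sup_over_cdfs(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal(9)
        b = rng.standard_normal(13) + 0.4
        d, _ = ks_compare(a, b)
        grid = np.concatenate([a, b])
        cdf_a = np.array([(a <= g).mean() for g in grid])
        cdf_b = np.array([(b <= g).mean() for g in grid])
        assert d == pytest.approx(np.abs(cdf_a - cdf_b).max())
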