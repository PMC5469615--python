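"""Multivariate permutation tests with max-|T| family-wise correction.

The pointwise test asks, at every timepoint of a trials x time matrix,
whether the response differs from the per-trial baseline.  Each trial's
baseline-window mean is subtracted, a one-sample t-statistic is computed
across trials at every timepoint, and the null distribution is built from
random sign flips of whole baseline-subtracted trial traces, recording the
maximum absolute T over time per flip.  Ranking |T(t)| in that max-null
yields pointwise p-values that control the family-wise error rate in
two-tailed tests (1000 permutations, alpha 0.05 by convention).
Contiguous runs of significant timepoints are reported as up/down segments
(the red/blue bars of the trial-average plots).

Sign flipping (rather than shuffling time) preserves within-trial
autocorrelation and matches the against-baseline, paired design.  Because
the per-timepoint sum of squares is invariant under sign flips, the entire
null distribution reduces to a single signs-by-data matrix product.

Also here: the generic two-sample permutation test used for response
strength/selectivity and the Kolmogorov-Smirnov comparison of cumulative
distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .photometry_erf import ERFMatrix
from .spike_peth import PETHMatrix

__all__ = ["PermTestResult", "maxt_test", "strength_perm_test", "ks_compare"]


@dataclass
class PermTestResult:
    """Pointwise T, family-wise corrected p, and significant segments.

    ``segments_up``/``segments_down`` are maximal runs (start s, end s)
    where p < alpha with positive/negative T.  p >= 1/(n_perm+1) always
    (add-one convention); with exhaustive enumeration p >= 1/2^n.
    """

    t_obs: np.ndarray
    p: np.ndarray
    alpha: float
    n_perm: int
    time_axis: np.ndarray
    segments_up: list[tuple[float, float]]
    segments_down: list[tuple[float, float]]
    exhaustive: bool = False


def _segments(
    sig: np.ndarray, positive: np.ndarray, time_axis: np.ndarray, dt: float
) -> tuple[list, list]:
    up, down = [], []
    i = 0
    n = sig.size
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] and positive[j + 1] == positive[i]:
            j += 1
        seg = (float(time_axis[i]), float(time_axis[j] + dt))
        (up if positive[i] else down).append(seg)
        i = j + 1
    return up, down


def _tstats(signed_means: np.ndarray, ssq: np.ndarray, n: int) -> np.ndarray:
    """One-sample t from per-flip means and the flip-invariant sum of squares."""
    var = (ssq - n * signed_means**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = signed_means / np.sqrt(var / n)
    return np.where(var > 0, t, 0.0)


def maxt_test(
    m: ERFMatrix | PETHMatrix,
    baseline_window: tuple[float, float],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermTestResult:
    """Max-|T| multivariate permutation test against the per-trial baseline.

    Parameters
    ----------
    m : ERFMatrix or PETHMatrix
        Trials x timepoints data (dF/F or firing rates).
    baseline_window : (s, s)
        Per-trial window whose mean is subtracted before testing.
    n_perm : int
        Random sign-flip draws (ignored when ``exhaustive``).
    exhaustive : bool
        Enumerate all 2^n sign assignments (n <= 20); p-values are then
        exact: p(t) = #{max|T*| >= |T(t)|} / 2^n.
    """
    data = m.values if isinstance(m, ERFMatrix) else m.rates
    n, n_t = data.shape
    if n < 2:
        raise ValueError("max-|T| test requires at least 2 trials")
    if not exhaustive and n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is 1/{n_perm + 1}")
    centered = data - m.window_means(baseline_window)[:, None]
    ssq = np.sum(centered**2, axis=0)
    t_obs = _tstats(centered.mean(axis=0), ssq, n)

    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration limited to n <= 20 trials")
        signs = np.array(
            [[1.0 if (k >> i) & 1 else -1.0 for i in range(n)] for k in range(2**n)]
        )
        n_draws = signs.shape[0]
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        n_draws = n_perm
    # max |T*| per flip via t^2 = n(n-1) mean^2 / (ssq - n mean^2);
    # ssq is invariant under sign flips, so one matmul gives every null draw
    m2 = signs @ centered
    m2 /= n
    np.square(m2, out=m2)
    denom = ssq[None, :] - n * m2
    np.clip(denom, 1e-300, None, out=denom)
    m2 *= n * (n - 1)
    m2 /= denom
    max_abs_t = np.sqrt(m2.max(axis=1))
    max_sorted = np.sort(max_abs_t)
    # ties at |T*| == |T| count as >= (conservative)
    geq = n_draws - np.searchsorted(max_sorted, np.abs(t_obs) - 1e-12, side="left")
    if exhaustive:
        p = geq / n_draws
    else:
        p = (1.0 + geq) / (n_draws + 1.0)
    dt = m.dt if isinstance(m, ERFMatrix) else m.bin_width
    up, down = _segments(p < alpha, t_obs > 0, m.time_axis, dt)
    return PermTestResult(
        t_obs, p, alpha, n_draws, np.asarray(m.time_axis), up, down, exhaustive=exhaustive
    )


def strength_perm_test(
    values_a,
    values_b,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> float:
    """Two-sample permutation p on the difference of means (two-tailed).

    Labels are shuffled between the groups; by default the test enumerates
    all splits exactly when C(n_a+n_b, n_a) <= 4096, otherwise draws
    ``n_perm`` random shuffles with the add-one correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    na = a.size
    d_obs = abs(a.mean() - b.mean())
    from math import comb

    n_splits = comb(pooled.size, na)
    if exhaustive is None:
        exhaustive = n_splits <= 4096
    tol = 1e-12 * (1.0 + abs(d_obs))
    if exhaustive:
        count = 0
        idx_all = set(range(pooled.size))
        for pick in combinations(range(pooled.size), na):
            ga = pooled[list(pick)]
            gb = pooled[list(idx_all - set(pick))]
            if abs(ga.mean() - gb.mean()) >= d_obs - tol:
                count += 1
        return count / n_splits
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:na].mean() - perm[na:].mean()) >= d_obs - tol:
            count += 1
    return (1.0 + count) / (n_perm + 1.0)


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: (D statistic, asymptotic p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
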