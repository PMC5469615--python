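"""Sliding-window ROC/AUC activation-inhibition and selectivity profiles.

For each 200 ms test window advanced in 50 ms steps across the trial, the
per-trial mean dF/F in the window is compared to the per-trial mean in a
fixed 200 ms control window 1.8 s before trial onset (-2 to -1.8 s).
The AUC is P(test > control) + 0.5 P(test = control), computed by ranks
(the Mann-Whitney U statistic divided by n_a * n_b): values above 0.5
indicate activation, below 0.5 inhibition.  A label-shuffling permutation
gives a per-window p.  The between-condition variant compares two ERF
matrices window-by-window: AUC 1 means complete selectivity for the first
condition, 0 for the second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .photometry_erf import ERFMatrix
from .spike_peth import PETHMatrix

__all__ = ["ROCProfile", "auc_mann_whitney", "sliding_roc", "condition_roc", "CONTROL_ROC_WINDOW"]

#: Fixed ROC control window: the 200 ms ending 1.8 s before trial onset.
CONTROL_ROC_WINDOW = (-2.0, -1.8)


@dataclass
class ROCProfile:
    """Per-window AUC (0-1) with optional permutation p-values.

    ``window_centers`` are the centers (s) of the test windows;
    ``degenerate`` flags windows where both distributions were identical
    constants (AUC pinned to 0.5).
    """

    window_centers: np.ndarray
    auc: np.ndarray
    p: np.ndarray
    test_width: float
    step: float
    control_window: tuple[float, float] | None
    degenerate: np.ndarray | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc))


def auc_mann_whitney(a, b) -> float:
    """AUC = P(a > b) + 0.5 P(a = b), via midranks of the pooled sample.

    Equals the Mann-Whitney U statistic divided by n_a * n_b, and exactly
    matches enumeration over all ordered pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def _windows(time_axis: np.ndarray, dt: float, width: float, step: float) -> list[slice]:
    """Slices of consecutive test windows; windows exceeding the axis are dropped."""
    n_per = int(round(width / dt))
    n_step = max(int(round(step / dt)), 1)
    out = []
    start = 0
    while start + n_per <= time_axis.size:
        out.append(slice(start, start + n_per))
        start += n_step
    return out


def _perm_p(a: np.ndarray, b: np.ndarray, auc: float, n_perm: int, rng) -> float:
    pooled = np.concatenate([a, b])
    na = a.size
    d_obs = abs(auc - 0.5)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(auc_mann_whitney(perm[:na], perm[na:]) - 0.5) >= d_obs - 1e-12:
            count += 1
    return (1.0 + count) / (n_perm + 1.0)


def sliding_roc(
    m: ERFMatrix | PETHMatrix,
    test_width: float = 0.2,
    step: float = 0.05,
    control_window: tuple[float, float] = CONTROL_ROC_WINDOW,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ROCProfile:
    """Activation/inhibition ROC profile against a fixed control window.

    ``n_perm=0`` skips the permutation p-values (p = NaN), which is useful
    when only the AUC profile is needed.
    """
    data = m.values if isinstance(m, ERFMatrix) else m.rates
    if data.shape[0] < 2:
        raise ValueError("sliding ROC requires at least 2 trials")
    dt = m.dt if isinstance(m, ERFMatrix) else m.bin_width
    ctrl = m.window_means(control_window)
    slices = _windows(m.time_axis, dt, test_width, step)
    rng = np.random.default_rng(seed)
    aucs = np.empty(len(slices))
    ps = np.full(len(slices), np.nan)
    centers = np.empty(len(slices))
    degen = np.zeros(len(slices), dtype=bool)
    for i, sl in enumerate(slices):
        a = data[:, sl].mean(axis=1)
        centers[i] = float(m.time_axis[sl].mean())
        if np.ptp(a) == 0 and np.ptp(ctrl) == 0 and a[0] == ctrl[0]:
            aucs[i] = 0.5
            degen[i] = True
            continue
        aucs[i] = auc_mann_whitney(a, ctrl)
        if n_perm > 0:
            ps[i] = _perm_p(a, ctrl, aucs[i], n_perm, rng)
    return ROCProfile(centers, aucs, ps, test_width, step, control_window, degen)


def condition_roc(
    m1: ERFMatrix | PETHMatrix,
    m2: ERFMatrix | PETHMatrix,
    test_width: float = 0.2,
    step: float = 0.05,
    n_perm: int = 0,
    seed: int | None = None,
) -> ROCProfile:
    """Selectivity ROC between two conditions sharing a time axis.

    Per window, the AUC between the two conditions' per-trial window means:
    1 = complete selectivity for condition 1, 0 = for condition 2.
    """
    d1 = m1.values if isinstance(m1, ERFMatrix) else m1.rates
    d2 = m2.values if isinstance(m2, ERFMatrix) else m2.rates
    if d1.shape[0] < 2 or d2.shape[0] < 2:
        raise ValueError("each condition requires at least 2 trials")
    if m1.time_axis.size != m2.time_axis.size or not np.allclose(m1.time_axis, m2.time_axis):
        raise ValueError("conditions must share the same time axis")
    dt = m1.dt if isinstance(m1, ERFMatrix) else m1.bin_width
    slices = _windows(m1.time_axis, dt, test_width, step)
    rng = np.random.default_rng(seed)
    aucs = np.empty(len(slices))
    ps = np.full(len(slices), np.nan)
    centers = np.empty(len(slices))
    for i, sl in enumerate(slices):
        a = d1[:, sl].mean(axis=1)
        b = d2[:, sl].mean(axis=1)
        centers[i] = float(m1.time_axis[sl].mean())
        aucs[i] = auc_mann_whitney(a, b)
        if n_perm > 0:
            ps[i] = _perm_p(a, b, aucs[i], n_perm, rng)
    return ROCProfile(centers, aucs, ps, test_width, step, None)
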