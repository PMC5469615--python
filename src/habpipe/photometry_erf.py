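"""dF/F computation, event alignment, and event-related response metrics.

Raw fluorescence is smoothed with a 20 ms moving average, segmented around
behavioral event onsets, and converted to fractional change
``dF/F = (F - F0) / F0`` where ``F0`` is the mean fluorescence over a
per-trial control window (default 1.5 s long, ending 0.5 s before the
event; social-interaction analyses use a window ending 3.5 s before onset
to avoid chasing-induced activity).  Response metrics summarize the mean
event-related fluorescence (ERF): peak dF/F, time-to-peak, a
mono-exponential decay constant fitted from the peak onward, and the AUC
(sum of the transient over a named window).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .session_io import EventStream, Recording

log = logging.getLogger("habpipe")

__all__ = [
    "ERFMatrix",
    "ERFSummary",
    "ResponseMetrics",
    "smooth_trace",
    "compute_dff",
    "erf_summary",
    "response_metrics",
    "block_average",
    "learning_onset",
    "BASELINE_WINDOW",
    "SOCIAL_BASELINE_WINDOW",
    "ALIGN_WINDOW",
]

#: Default per-trial baseline: 1.5 s long, ending 0.5 s before event onset.
BASELINE_WINDOW = (-2.0, -0.5)
#: Social-interaction baseline: same length, ending 3.5 s before onset.
SOCIAL_BASELINE_WINDOW = (-5.0, -3.5)
#: Default alignment window around event onset.
ALIGN_WINDOW = (-2.0, 10.0)


@dataclass
class ERFMatrix:
    """Trials x timepoints dF/F aligned to event onsets.

    ``time_axis`` is seconds relative to onset, uniform step 1/rate.
    ``trial_order`` records the original event indices of the retained rows.
    """

    values: np.ndarray
    time_axis: np.ndarray
    event_label: str = ""
    trial_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.values.shape[1] != self.time_axis.size:
            raise ValueError("values and time_axis disagree on the number of timepoints")
        if self.time_axis.size >= 2:
            dt = np.diff(self.time_axis)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time_axis must be strictly increasing and uniform")
        if self.trial_order is None:
            self.trial_order = np.arange(self.values.shape[0])

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def dt(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0]) if self.time_axis.size > 1 else np.nan

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Index slice covering [window[0], window[1]) on the time axis."""
        i0 = int(np.searchsorted(self.time_axis, window[0] - 1e-9))
        i1 = int(np.searchsorted(self.time_axis, window[1] - 1e-9))
        if i1 <= i0:
            raise ValueError(f"window {window} does not cover any timepoint")
        return slice(i0, i1)

    def window_means(self, window: tuple[float, float]) -> np.ndarray:
        """Per-trial mean dF/F over a time window."""
        return self.values[:, self.window_slice(window)].mean(axis=1)


@dataclass
class ERFSummary:
    """Pointwise mean and SEM of an ERF matrix (the thick-line/shaded-area plot)."""

    mean: np.ndarray
    sem: np.ndarray
    time_axis: np.ndarray
    n_trials: int
    single_trial: bool = False


@dataclass
class ResponseMetrics:
    """Summary of a mean event-related transient.

    peak_dff : maximum dF/F within the response window (fraction)
    t_peak : time from event onset to that peak, s
    tau_decay : mono-exponential decay constant fitted from the peak to the
        end of the response window, s (NaN when the fit is skipped)
    auc : sum of dF/F samples over the window (dF/F * samples)
    tau_flagged : True when the tau fit was skipped (non-positive peak) or
        failed to converge
    """

    peak_dff: float
    t_peak: float
    tau_decay: float
    auc: float
    tau_flagged: bool = False


def smooth_trace(rec: Recording, span: float = 0.020) -> Recording:
    """Centered moving-average smoothing (default 20 ms span).

    Edge samples use shrunken windows, so the output length equals the
    input length and a constant trace is unchanged.
    """
    w = int(round(span * rec.rate))
    if w < 1:
        raise ValueError(f"span {span} s is shorter than one sample at {rec.rate} Hz")
    n = rec.trace.size
    if w > n:
        raise ValueError(f"span {span} s exceeds the trace duration")
    if w == 1:
        return Recording(rec.trace.copy(), rec.rate, rec.t0, rec.channel_label)
    # window [i - w//2, i + (w-1)//2] clipped to the trace, via cumulative sums
    csum = np.concatenate([[0.0], np.cumsum(rec.trace)])
    idx = np.arange(n)
    lo = np.clip(idx - w // 2, 0, n)
    hi = np.clip(idx + (w - 1) // 2 + 1, 0, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return Recording(out, rec.rate, rec.t0, rec.channel_label)


def compute_dff(
    rec: Recording,
    events: EventStream,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    window: tuple[float, float] = ALIGN_WINDOW,
    label: str | None = None,
) -> ERFMatrix:
    """Segment and align the trace to event onsets and convert to dF/F.

    Per trial, ``F0`` is the mean raw (smoothed) fluorescence over
    ``baseline_window`` relative to that event's onset, and the row is
    ``(F - F0)/F0`` over ``window``.  Trials whose alignment window falls
    outside the recording, or whose ``F0 <= 0``, are excluded with a
    warning; if every trial is excluded an error is raised.
    """
    ev = events if label is None else events.select(label)
    if len(ev) == 0:
        raise ValueError("no events to align" + (f" with label {label!r}" if label else ""))
    if baseline_window[0] < window[0] or baseline_window[1] > window[1]:
        # baseline need only lie within the available pre-event segment;
        # widen the cut so F0 can always be computed
        cut = (min(window[0], baseline_window[0]), max(window[1], baseline_window[1]))
    else:
        cut = window
    rate = rec.rate
    i_lo = int(round(cut[0] * rate))
    n_out = int(round((window[1] - window[0]) * rate))
    off_w = int(round(window[0] * rate))
    b0 = int(round(baseline_window[0] * rate))
    b1 = int(round(baseline_window[1] * rate))
    rows, kept = [], []
    for j, onset in enumerate(ev.onsets):
        i_on = int(round((onset - rec.t0) * rate))
        if i_on + i_lo < 0 or i_on + off_w + n_out > rec.trace.size or i_on + b0 < 0:
            log.warning("trial %d at t=%.3f s truncated by recording bounds; excluded", j, onset)
            continue
        f0 = float(rec.trace[i_on + b0 : i_on + b1].mean())
        if f0 <= 0:
            log.warning("trial %d at t=%.3f s has non-positive baseline F0=%.3g; excluded", j, onset, f0)
            continue
        seg = rec.trace[i_on + off_w : i_on + off_w + n_out]
        rows.append((seg - f0) / f0)
        kept.append(j)
    if not rows:
        raise ValueError("all trials excluded: no valid baseline/alignment windows")
    time_axis = (np.arange(n_out) + off_w) / rate
    return ERFMatrix(
        np.asarray(rows),
        time_axis,
        event_label=label or "/".join(ev.vocabulary),
        trial_order=np.asarray(kept),
    )


def erf_summary(m: ERFMatrix) -> ERFSummary:
    """Pointwise mean and SEM across trials (SEM = sd/sqrt(n), ddof=1)."""
    n = m.n_trials
    if n < 1:
        raise ValueError("ERF matrix has no trials")
    mean = m.values.mean(axis=0)
    if n == 1:
        return ERFSummary(mean, np.zeros_like(mean), m.time_axis, 1, single_trial=True)
    sem = m.values.std(axis=0, ddof=1) / np.sqrt(n)
    return ERFSummary(mean, sem, m.time_axis, n)


def _fit_tau(t: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Least-squares mono-exponential A exp(-t/tau); tau seeded at 1/e crossing."""
    peak = y[0]
    below = np.nonzero(y <= peak / np.e)[0]
    tau0 = float(t[below[0]]) if below.size else float(t[-1])
    tau0 = max(tau0, (t[1] - t[0]) if t.size > 1 else 1e-3)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda x, a, tau: a * np.exp(-x / tau),
                t,
                y,
                p0=(peak, tau0),
                bounds=((0.0, 1e-6), (np.inf, np.inf)),
                method="trf",
                maxfev=2000,
            )
        return float(popt[1]), False
    except (RuntimeError, ValueError):
        return float("nan"), True


def response_metrics(
    m: ERFMatrix | ERFSummary,
    response_window: tuple[float, float] = (0.0, 10.0),
) -> ResponseMetrics:
    """Peak, time-to-peak, decay tau and AUC of the mean ERF.

    The peak is the maximum of the trial-averaged trace within
    ``response_window``; tau comes from a trust-region least-squares
    mono-exponential fit from the peak to the window end.  A non-positive
    peak skips the tau fit and flags the result.
    """
    if isinstance(m, ERFSummary):
        mean, axis = m.mean, m.time_axis
        sl = slice(
            int(np.searchsorted(axis, response_window[0] - 1e-9)),
            int(np.searchsorted(axis, response_window[1] - 1e-9)),
        )
    else:
        mean, axis = m.values.mean(axis=0), m.time_axis
        sl = m.window_slice(response_window)
    seg = mean[sl]
    seg_t = axis[sl]
    if seg.size == 0:
        raise ValueError(f"response window {response_window} is empty on this axis")
    i_pk = int(np.argmax(seg))
    peak = float(seg[i_pk])
    t_peak = float(seg_t[i_pk])
    auc = float(seg.sum())
    if peak <= 0 or i_pk >= seg.size - 2:
        return ResponseMetrics(peak, t_peak, float("nan"), auc, tau_flagged=True)
    tail_t = seg_t[i_pk:] - seg_t[i_pk]
    tau, flagged = _fit_tau(tail_t, seg[i_pk:])
    return ResponseMetrics(peak, t_peak, tau, auc, tau_flagged=flagged)


def zscore_erf(m: ERFMatrix, control_window: tuple[float, float] = BASELINE_WINDOW) -> np.ndarray:
    """Standardized mean ERF: (mean - mu_ctrl) / sd_ctrl over control bins.

    The photometry analogue of the spike Z-profile, used when clustering
    recording-site response profiles alongside unit PETHs.
    """
    mean = m.values.mean(axis=0)
    sl = m.window_slice(control_window)
    mu = float(mean[sl].mean())
    sd = float(mean[sl].std(ddof=1))
    if sd == 0.0:
        raise ValueError("control window has zero variance; z-profile undefined")
    return (mean - mu) / sd


def block_average(values: np.ndarray, block: int) -> np.ndarray:
    """Means of consecutive non-overlapping blocks of trials.

    The conditioning analyses average 5 consecutive trials (aversive) or 10
    (appetitive).  A trailing partial block is averaged over its actual size.
    """
    if block < 1:
        raise ValueError("block size must be >= 1")
    v = np.asarray(values, dtype=float)
    n_full, rem = divmod(v.size, block)
    out = []
    if n_full:
        out.append(v[: n_full * block].reshape(n_full, block).mean(axis=1))
    if rem:
        out.append(np.array([v[n_full * block :].mean()]))
    return np.concatenate(out) if out else np.empty(0)


def learning_onset(flags) -> int | None:
    """First 1-based block from which significance holds for all later blocks.

    ``flags`` is a boolean sequence of per-block significance calls.
    Returns ``None`` when the criterion is never sustained to the end.
    """
    f = np.asarray(flags, dtype=bool)
    if f.size < 2:
        raise ValueError("need at least 2 blocks")
    if not f[-1]:
        return None
    # last index where the flag is False, +1 -> first sustained block (0-based)
    false_idx = np.nonzero(~f)[0]
    start = int(false_idx[-1]) + 1 if false_idx.size else 0
    return start + 1
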