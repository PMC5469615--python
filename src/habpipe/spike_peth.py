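"""Peri-event time histograms, Gaussian smoothing, and z-standardization.

Spike rates are binned at 50 ms around event onsets, optionally smoothed
with a Gaussian kernel (sigma = 50 ms), and standardized against the mean
and SD of a pre-event control period (default [-2, 0] s), yielding the
Z-profiles used for population heatmaps and response-type clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .session_io import EventStream, SpikeUnit

__all__ = ["PETHMatrix", "ZProfile", "peth", "gaussian_smooth", "zscore_profile", "CONTROL_WINDOW"]

#: Default control period for z-standardization: the 2 s preceding the event.
CONTROL_WINDOW = (-2.0, 0.0)


@dataclass
class PETHMatrix:
    """Trials x bins firing rates (spikes/s) on a uniform bin grid.

    ``time_axis`` holds bin centers in seconds relative to event onset.
    """

    rates: np.ndarray
    bin_width: float
    time_axis: np.ndarray
    smoothing_sigma: float | None = None

    def __post_init__(self) -> None:
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.rates.shape[1] != self.time_axis.size:
            raise ValueError("rates and time_axis disagree on bin count")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be > 0")

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Bins whose centers lie in [window[0], window[1])."""
        i0 = int(np.searchsorted(self.time_axis, window[0] - 1e-9))
        i1 = int(np.searchsorted(self.time_axis, window[1] - 1e-9))
        if i1 <= i0:
            raise ValueError(f"window {window} covers no bins")
        return slice(i0, i1)

    def window_means(self, window: tuple[float, float]) -> np.ndarray:
        return self.rates[:, self.window_slice(window)].mean(axis=1)


@dataclass
class ZProfile:
    """Standardized trial-averaged rate per bin.

    z = (mean rate - mu_ctrl) / sd_ctrl, with mu/sd taken over the control
    window's bins of the trial-averaged profile.  ``flagged`` marks units
    with zero control-window variance (z undefined).
    """

    z: np.ndarray
    time_axis: np.ndarray
    control_window: tuple[float, float]
    flagged: bool = False


def peth(
    unit: SpikeUnit,
    events: EventStream,
    window: tuple[float, float] = (-2.0, 10.0),
    bin_width: float = 0.05,
    label: str | None = None,
) -> PETHMatrix:
    """Per-trial spike counts in fixed bins around event onsets, as rates.

    Counts are conserved: the summed (rate * bin_width) over a row equals
    the number of spikes inside that trial's window.
    """
    ev = events if label is None else events.select(label)
    if len(ev) == 0:
        raise ValueError("no events to align")
    n_bins = int(round((window[1] - window[0]) / bin_width))
    if n_bins < 1:
        raise ValueError("window spans less than one bin")
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    # searchsorted on the (sorted) spike train, one call for all trial edges
    all_edges = ev.onsets[:, None] + edges[None, :]
    pos = np.searchsorted(unit.spike_times, all_edges.ravel()).reshape(len(ev), n_bins + 1)
    counts = np.diff(pos, axis=1).astype(float)
    centers = edges[:-1] + bin_width / 2.0
    return PETHMatrix(counts / bin_width, bin_width, centers)


def gaussian_smooth(p: PETHMatrix, sigma: float = 0.05) -> PETHMatrix:
    """Per-trial convolution with a normalized Gaussian (sigma = 50 ms default).

    The kernel is truncated at +-4 sigma; edges are handled by reflection,
    which preserves row integrals away from the boundaries.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    sig_bins = sigma / p.bin_width
    sm = gaussian_filter1d(p.rates, sig_bins, axis=1, mode="reflect", truncate=4.0)
    return PETHMatrix(sm, p.bin_width, p.time_axis, smoothing_sigma=sigma)


def zscore_profile(
    p: PETHMatrix, control_window: tuple[float, float] = CONTROL_WINDOW
) -> ZProfile:
    """Standard scores of the trial-averaged rate against a control period.

    mu and sd are computed across the control window's bins of the
    trial-averaged profile (>= 2 bins required).  Units with sd == 0 are
    flagged and their z left as NaN.
    """
    sl = p.window_slice(control_window)
    if sl.stop - sl.start < 2:
        raise ValueError("control window must contain at least 2 bins")
    mean_rate = p.rates.mean(axis=0)
    mu = float(mean_rate[sl].mean())
    sd = float(mean_rate[sl].std(ddof=1))
    if sd == 0.0:
        return ZProfile(np.full_like(mean_rate, np.nan), p.time_axis, control_window, flagged=True)
    return ZProfile((mean_rate - mu) / sd, p.time_axis, control_window)
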