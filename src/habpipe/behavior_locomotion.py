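"""Locomotor speed from position traces and cue-window trial summaries.

Speed is the rate of body-position change: Euclidean displacement divided
by the time step between adjacent video frames.  Conditioning analyses
average the speed over the 4 s following cue onset (0-4 s) per trial, then
block-average across consecutive trials (5 for aversive sessions, 10 for
appetitive) to track learning-related locomotor suppression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .photometry_erf import block_average
from .session_io import EventStream, PositionTrace

log = logging.getLogger("habpipe")

__all__ = ["SpeedTrace", "speed_from_positions", "cue_window_speed"]


@dataclass
class SpeedTrace:
    """Instantaneous speed (cm/s) at midpoint times of adjacent position pairs."""

    times: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.times.size != self.speed.size:
            raise ValueError("times and speed must have equal length")


def speed_from_positions(p: PositionTrace, median_span: int = 0) -> SpeedTrace:
    """Speed = |displacement| / dt per adjacent position pair.

    ``median_span`` > 1 applies a median filter to the positions first
    (optional tracking-noise suppression; off by default).
    """
    if p.times.size < 2:
        raise ValueError("need at least 2 position samples")
    dts = np.diff(p.times)
    if np.any(dts <= 0):
        raise ValueError("duplicate or non-increasing timestamps in position trace")
    xy = p.xy
    if median_span > 1:
        xy = median_filter(xy, size=(median_span, 1), mode="nearest")
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    mid = p.times[:-1] + dts / 2.0
    return SpeedTrace(mid, disp / dts)


def cue_window_speed(
    s: SpeedTrace,
    events: EventStream,
    window: tuple[float, float] = (0.0, 4.0),
    label: str | None = None,
    block: int | None = None,
) -> np.ndarray:
    """Mean speed per trial over ``window`` after each event onset.

    Trials whose window is not fully covered by the speed trace are
    excluded with a warning.  With ``block`` set, returns block means
    (5 consecutive trials for aversive sessions, 10 for appetitive).
    """
    ev = events if label is None else events.select(label)
    if len(ev) == 0:
        raise ValueError("no events")
    out = []
    for j, onset in enumerate(ev.onsets):
        lo, hi = onset + window[0], onset + window[1]
        if lo < s.times[0] or hi > s.times[-1]:
            log.warning("trial %d window [%.2f, %.2f] s truncated; excluded", j, lo, hi)
            continue
        mask = (s.times >= lo) & (s.times < hi)
        out.append(float(s.speed[mask].mean()))
    per_trial = np.asarray(out)
    if block is not None:
        return block_average(per_trial, block)
    return per_trial
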