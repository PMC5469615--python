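"""Optogenetic identification of units (tagging).

A unit counts as optically tagged when (i) the Pearson correlation C
between its spontaneous and light-evoked mean waveforms exceeds 0.85, and
(ii) the bootstrap p-value of its light-locked response is below 0.001.
The response is summarized by the first-spike latencies L after each pulse
and the reliability R of evoked spiking within 10 ms of light onset.

The bootstrap null places surrogate pulse trains — same pulse count and
10 Hz spacing, shifted rigidly — uniformly within the stimulation-free
epochs of the recording and recomputes the statistic per surrogate.  The
default statistic is the reliability R (robust at low spontaneous rates);
a median-latency variant is available via ``statistic="median_latency"``.
p = (1 + #{surrogate >= observed}) / (n_boot + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session_io import SpikeUnit

__all__ = [
    "TagResult",
    "waveform_correlation",
    "evoked_latency_reliability",
    "tagging_pvalue",
    "tag_unit",
    "C_THRESHOLD",
    "P_THRESHOLD",
    "EVOKED_WINDOW",
]

C_THRESHOLD = 0.85
P_THRESHOLD = 0.001
#: Window after light onset within which an evoked spike must occur.
EVOKED_WINDOW = 0.010


@dataclass
class TagResult:
    """Tagging decision: tagged iff c > 0.85 and p < 0.001 (strict)."""

    c: float
    latencies: np.ndarray
    r: float
    p: float
    tagged: bool
    c_flagged: bool = False


def waveform_correlation(wf_spont: np.ndarray, wf_evoked: np.ndarray) -> float:
    """Pearson correlation of concatenated per-channel mean waveforms.

    Returns NaN for constant waveforms (correlation undefined).
    """
    a = np.asarray(wf_spont, dtype=float).ravel()
    b = np.asarray(wf_evoked, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("waveforms must have equal total length")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _first_spike_latencies(
    spikes: np.ndarray, pulses: np.ndarray, window: float
) -> tuple[np.ndarray, float]:
    """Per pulse, latency of the first spike in (onset, onset+window]; plus R."""
    if pulses.size == 0:
        raise ValueError("unit has no light pulses")
    if spikes.size == 0:
        return np.empty(0), 0.0
    first = np.searchsorted(spikes, pulses, side="right")
    has = (first < spikes.size) & (spikes[np.clip(first, 0, spikes.size - 1)] <= pulses + window)
    lat = spikes[np.clip(first, 0, spikes.size - 1)] - pulses
    return lat[has], float(has.mean())


def evoked_latency_reliability(
    unit: SpikeUnit, window: float = EVOKED_WINDOW
) -> tuple[np.ndarray, float]:
    """First-spike latencies after each pulse and the reliability R.

    R is the fraction of pulses followed by a spike within ``window`` (10 ms).
    """
    return _first_spike_latencies(unit.spike_times, unit.light_pulses, window)


def tagging_pvalue(
    unit: SpikeUnit,
    window: float = EVOKED_WINDOW,
    n_boot: int = 1000,
    seed: int | None = None,
    statistic: str = "reliability",
) -> float:
    """Bootstrap p for light-locked spiking against shifted surrogate trains.

    The recording must contain stimulation-free epochs totalling at least
    10x the pulse-train span.  Surrogates preserve the within-train pulse
    spacing (the whole train is shifted), so within-train dependence of
    spontaneous spiking is kept intact under the null.
    """
    if statistic not in ("reliability", "median_latency"):
        raise ValueError("statistic must be 'reliability' or 'median_latency'")
    pulses = unit.light_pulses
    if pulses.size == 0:
        raise ValueError("unit has no light pulses")
    t0, t1 = unit.epoch()
    span = float(pulses[-1] - pulses[0])
    # stimulation-free epochs on either side of the train (with a margin)
    margin = 1.0
    free = []  # ranges of allowed surrogate train-start offsets
    free_dur = 0.0
    pre = pulses[0] - margin - t0
    if pre > span:
        free.append((t0, pulses[0] - margin - span))
        free_dur += pre
    post = t1 - (pulses[-1] + window + margin)
    if post > span:
        free.append((pulses[-1] + window + margin, t1 - span))
        free_dur += post
    if not free or free_dur < 10.0 * max(span, 1e-9):
        raise ValueError(
            "insufficient stimulation-free epoch: need total duration >= 10x the pulse-train span"
        )
    lat, r_obs = _first_spike_latencies(unit.spike_times, pulses, window)
    if statistic == "reliability":
        obs = r_obs
    else:
        # locked units have *small* median latency; rank the negation
        obs = -float(np.median(lat)) if lat.size else -np.inf

    rng = np.random.default_rng(seed)
    # draw surrogate train-start offsets uniformly over the free epochs
    lens = np.array([b - a for a, b in free])
    starts_lo = np.array([a for a, _ in free])
    pick = rng.choice(len(free), size=n_boot, p=lens / lens.sum())
    offs = starts_lo[pick] + rng.random(n_boot) * lens[pick]
    rel_pulses = pulses - pulses[0]
    count = 0
    for off in offs:
        s_lat, s_r = _first_spike_latencies(unit.spike_times, off + rel_pulses, window)
        if statistic == "reliability":
            s = s_r
        else:
            s = -float(np.median(s_lat)) if s_lat.size else -np.inf
        if s >= obs - 1e-12:
            count += 1
    return (1.0 + count) / (n_boot + 1.0)


def tag_unit(
    unit: SpikeUnit,
    window: float = EVOKED_WINDOW,
    n_boot: int = 1000,
    seed: int | None = None,
    statistic: str = "reliability",
) -> TagResult:
    """Full tagging decision: waveform C, latencies, R, bootstrap p.

    The evoked waveform is taken from ``unit.waveform_evoked`` when present;
    otherwise C cannot be computed and is flagged (NaN, not tagged).
    """
    if unit.waveform_evoked is not None:
        c = waveform_correlation(unit.waveform_mean, unit.waveform_evoked)
    else:
        c = float("nan")
    lat, r = evoked_latency_reliability(unit, window)
    p = tagging_pvalue(unit, window, n_boot, seed, statistic)
    c_ok = bool(np.isfinite(c) and c > C_THRESHOLD)
    tagged = c_ok and p < P_THRESHOLD
    return TagResult(c, lat, r, p, tagged, c_flagged=not np.isfinite(c))
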