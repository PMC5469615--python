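"""Synthetic photometry sessions, spike units, tagging epochs and locomotion.

The generators emulate the statistical structure of trial-aligned lateral
habenula recordings so that every downstream stage of the pipeline has a
ground-truth test bed:

* GCaMP-like Ca2+ transients with stimulus-specific peak amplitude,
  time-to-peak and decay time constant.  The built-in presets use the group
  statistics reported for intra-oral quinine (27.8% dF/F, peak 0.68 s,
  tau 5.88 s), footshock (48.8%, 0.26 s, 1.89 s) and social attack
  (32.9%, 0.57 s, 7.80 s).
* Tonic units firing ~30 spikes/s with cue/reward inhibition (25 and
  20 spikes/s) and, for "type II" profiles, a post-inhibitory rebound.
* Learning-dependent cue responses: a logistic per-trial gain with
  half-point around trial 7 for aversive conditioning (significant within
  5-10 trials) and around trial 135 for appetitive conditioning
  (significant after ~120-150 trials).
* Light-locked evoked spikes for optogenetic tagging (5 ms pulses, 10 Hz).

Transient kernel
----------------
A difference of exponentials ``k(t) = c (exp(-t/tau_d) - exp(-t/tau_r))``
with ``tau_r`` solved numerically so the peak falls at ``t_peak`` given the
decay constant, and ``c`` normalizing the peak to 1.  Transients multiply
the photobleaching baseline, ``F(t) = B(t) (1 + sum_i a_i k(t - t_i) + eps)``
with ``B(t) = exp(-t/drift_tau)``, so the dF/F amplitude recovered against a
local baseline equals the preset amplitude irrespective of bleaching.

Every generator is deterministic: a fixed seed yields byte-identical output,
and per-unit streams are keyed by (master seed, unit index) so generating a
population in any order gives identical per-unit data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .session_io import EventStream, PositionTrace, Recording, SpikeUnit

__all__ = [
    "TransientPreset",
    "KernelComponent",
    "SpikeProfilePreset",
    "LearningSchedule",
    "TaggingPreset",
    "MixtureSpec",
    "TrialLayout",
    "TRANSIENT_PRESETS",
    "SPIKE_PRESETS",
    "SITE_PRESETS",
    "LAYOUTS",
    "transient_kernel",
    "solve_rise_tau",
    "gen_trial_events",
    "gen_photometry_session",
    "gen_spike_unit",
    "gen_tagging_epoch",
    "gen_population",
    "gen_photometry_population",
    "gen_locomotion",
    "spike_rate_function",
]

PHOTOMETRY_RATE = 500.0  # Hz, acquisition digitization rate


def _rng(seed, *key) -> np.random.Generator:
    """Deterministic generator keyed by (seed, *key); order-independent."""
    if isinstance(seed, np.random.Generator):
        if key:
            raise ValueError("cannot derive keyed streams from a live Generator")
        return seed
    entropy = [0 if seed is None else int(seed), *[int(k) for k in key]]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransientPreset:
    """Single-stimulus Ca2+ transient statistics.

    amplitude : peak dF/F as a fraction (0.278 = 27.8%)
    t_peak : time from event onset to peak, s
    tau_decay : mono-exponential decay constant, s
    amplitude_cv : across-trial coefficient of variation (lognormal)
    noise_sd : additive sample noise, dF/F units at the acquisition rate
    drift_tau : photobleaching time constant, s
    """

    amplitude: float
    t_peak: float
    tau_decay: float
    amplitude_cv: float = 0.3
    noise_sd: float = 0.01
    drift_tau: float = 2000.0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.t_peak < 0 or self.noise_sd < 0:
            raise ValueError("amplitude, t_peak and noise_sd must be >= 0")
        if not self.tau_decay > 0:
            raise ValueError("tau_decay must be > 0")


@dataclass(frozen=True)
class KernelComponent:
    """One event-locked transient component of a photometry site profile.

    ``amplitude`` is signed (negative = inhibition of the bulk Ca2+ signal);
    ``learned`` components are additionally scaled by the session's
    :class:`LearningSchedule` gain for their trial.
    """

    label: str
    amplitude: float
    t_peak: float
    tau_decay: float
    offset: float = 0.0
    learned: bool = False


@dataclass(frozen=True)
class SpikeProfilePreset:
    """Firing-rate profile of a reward-conditioned unit.

    Baseline ~30 spikes/s, reduced to ~25 during the cue+delay and ~20
    following sucrose.  ``type2`` profiles rebound above baseline after the
    inhibition (peak ``rebound_rate``, decay ``rebound_tau``); ``type1``
    profiles recover monotonically (``rebound_rate <= baseline_rate``).
    """

    baseline_rate: float = 30.0
    cue_rate: float = 25.0
    us_rate: float = 20.0
    rebound_rate: float = 20.0
    rebound_tau: float = 1.5
    profile_type: str = "type1"

    def __post_init__(self) -> None:
        for r in (self.baseline_rate, self.cue_rate, self.us_rate, self.rebound_rate):
            if r < 0:
                raise ValueError("firing rates must be >= 0")
        if self.profile_type not in ("type1", "type2"):
            raise ValueError("profile_type must be 'type1' or 'type2'")
        if self.profile_type == "type1" and self.rebound_rate > self.baseline_rate:
            raise ValueError("type1 profiles require rebound_rate <= baseline_rate")


@dataclass(frozen=True)
class LearningSchedule:
    """Logistic per-trial gain on the cue-locked response.

    gain(trial) = 1 / (1 + exp(-k (trial - h))): ~0 on trial 1, asymptote 1.
    ``h`` is the half-point trial, ``k`` the steepness.  Aversive
    conditioning uses h=7 (responses significant within 5-10 trials);
    appetitive uses h=135 (significant after ~120-150 trials).
    """

    h: float = 7.0
    k: float = 0.8
    direction: str = "excitatory"

    def __post_init__(self) -> None:
        if self.direction not in ("excitatory", "inhibitory"):
            raise ValueError("direction must be 'excitatory' or 'inhibitory'")
        if self.k <= 0:
            raise ValueError("steepness k must be > 0")

    def gain(self, trial) -> np.ndarray | float:
        """Gain for 1-based trial number(s); monotone increasing in trial."""
        t = np.asarray(trial, dtype=float)
        g = 1.0 / (1.0 + np.exp(-self.k * (t - self.h)))
        return float(g) if g.ndim == 0 else g

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "excitatory" else -1.0


AVERSIVE_SCHEDULE = LearningSchedule(h=7.0, k=0.8, direction="excitatory")
APPETITIVE_SCHEDULE = LearningSchedule(h=135.0, k=0.05, direction="inhibitory")


@dataclass(frozen=True)
class TaggingPreset:
    """Optogenetic tagging epoch parameters (5 ms pulses at 10 Hz)."""

    latency_mean: float = 0.003
    latency_jitter: float = 0.001
    reliability: float = 0.9
    spont_rate: float = 30.0
    n_pulses: int = 600
    pulse_rate: float = 10.0
    pulse_width: float = 0.005
    waveform_perturbation: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError("reliability must lie in [0, 1]")
        if self.latency_mean < 0:
            raise ValueError("latency_mean must be >= 0")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")


@dataclass(frozen=True)
class TrialLayout:
    """Per-trial event template plus inter-trial spacing.

    ``events``: (offset from trial start, label, duration) triples.
    ``iti``: uniform range (s) of the gap between the end of one trial's
    last event and the start of the next trial.
    ``lead_in``: baseline recording before the first trial (s).
    ``us_probability``: per-label delivery probability (labels absent from
    the mapping are always delivered) — used for probabilistic-reward tasks.
    """

    events: tuple[tuple[float, str, float], ...]
    iti: tuple[float, float]
    lead_in: float = 10.0
    tail: float = 15.0
    us_probability: dict[str, float] = field(default_factory=dict)

    @property
    def span(self) -> float:
        return max(off + dur for off, _, dur in self.events)


# Layout presets follow the behavioral protocols: 0.5 s infusions with ITI
# 110-130 s (quinine) or 20-40 s (sucrose); conditioning trials are a 2 s
# tone, a 2 s delay, then a 0.5 s US.
LAYOUTS: dict[str, TrialLayout] = {
    "quinine": TrialLayout(events=((0.0, "us", 0.5),), iti=(110.0, 130.0)),
    "footshock": TrialLayout(events=((0.0, "us", 0.5),), iti=(20.0, 40.0)),
    "social": TrialLayout(events=((0.0, "attack_onset", 0.5),), iti=(20.0, 40.0), lead_in=12.0),
    "conditioning_quinine": TrialLayout(
        events=((0.0, "cue", 2.0), (4.0, "us", 0.5)), iti=(110.0, 130.0)
    ),
    "conditioning_footshock": TrialLayout(
        events=((0.0, "cue", 2.0), (4.0, "us", 0.5)), iti=(20.0, 40.0)
    ),
    "conditioning_sucrose": TrialLayout(
        events=((0.0, "cue", 2.0), (4.0, "us", 0.5)), iti=(20.0, 40.0)
    ),
    "extinction": TrialLayout(events=((0.0, "cue", 2.0),), iti=(20.0, 40.0)),
}

TRANSIENT_PRESETS: dict[str, TransientPreset] = {
    "quinine": TransientPreset(amplitude=0.278, t_peak=0.68, tau_decay=5.88),
    "footshock": TransientPreset(amplitude=0.488, t_peak=0.26, tau_decay=1.89),
    "social": TransientPreset(amplitude=0.329, t_peak=0.57, tau_decay=7.80),
}

SPIKE_PRESETS: dict[str, SpikeProfilePreset] = {
    "sucrose_type1": SpikeProfilePreset(profile_type="type1", rebound_rate=20.0, rebound_tau=1.0),
    "sucrose_type2": SpikeProfilePreset(profile_type="type2", rebound_rate=45.0, rebound_tau=1.5),
}

# Photometry site profiles for reward conditioning: type I sites show pure
# inhibition to cue and sucrose; type II sites add a post-inhibitory rebound
# locked to sucrose offset.  Amplitudes are mild relative to the aversive
# transients, matching the "mild and sustained reduction" the cue evokes.
SITE_PRESETS: dict[str, tuple[KernelComponent, ...]] = {
    "site_type1": (
        KernelComponent("cue", -0.06, 1.0, 2.5, learned=True),
        KernelComponent("us", -0.10, 0.6, 1.5),
    ),
    "site_type2": (
        KernelComponent("cue", -0.06, 1.0, 2.5, learned=True),
        KernelComponent("us", -0.10, 0.6, 1.5),
        KernelComponent("us", 0.15, 0.5, 2.0, offset=1.0),
    ),
}


@dataclass(frozen=True)
class MixtureSpec:
    """A population of units/sites sharing one trial schedule.

    ``counts`` maps profile names to unit counts; per-unit RNG streams are
    keyed by unit index so output is independent of generation order.
    The default compositions mirror the recorded ensembles: 37 type I + 33
    type II tagged units, and 9 + 9 photometry recording sites.
    """

    counts: dict[str, int]
    n_trials: int = 100
    layout: TrialLayout = field(default_factory=lambda: LAYOUTS["conditioning_sucrose"])
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("mixture counts must be >= 0")
        if sum(self.counts.values()) < 2:
            raise ValueError("mixture must contain at least 2 units")

    @property
    def members(self) -> list[str]:
        out: list[str] = []
        for name in sorted(self.counts):
            out.extend([name] * self.counts[name])
        return out


# ---------------------------------------------------------------------------
# Transient kernel
# ---------------------------------------------------------------------------

def solve_rise_tau(t_peak: float, tau_decay: float) -> float:
    """Rise constant tau_r of a difference-of-exponentials kernel.

    Solves ``t_peak = ln(tau_d/tau_r) * tau_d*tau_r / (tau_d - tau_r)`` for
    ``tau_r`` in (0, tau_d).  The peak time is monotone increasing in tau_r,
    approaching 0 as tau_r -> 0 and tau_d as tau_r -> tau_d.
    """
    if not 0 < t_peak < tau_decay:
        raise ValueError(f"t_peak must lie in (0, tau_decay); got {t_peak} vs {tau_decay}")

    def peak_time(tau_r: float) -> float:
        return math.log(tau_decay / tau_r) * tau_decay * tau_r / (tau_decay - tau_r)

    lo, hi = 1e-8 * tau_decay, (1.0 - 1e-9) * tau_decay
    return float(brentq(lambda x: peak_time(x) - t_peak, lo, hi, xtol=1e-12, rtol=1e-14))


def transient_kernel(t: np.ndarray, t_peak: float, tau_decay: float) -> np.ndarray:
    """Unit-peak transient kernel evaluated at times ``t`` (s, >= 0 support).

    ``t_peak == 0`` degenerates to an instantaneous-rise mono-exponential.
    """
    t = np.asarray(t, dtype=float)
    if t_peak == 0.0:
        k = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau_decay), 0.0)
        return k
    tau_r = solve_rise_tau(t_peak, tau_decay)
    tc = np.clip(t, 0, None)
    raw = np.exp(-tc / tau_decay) - np.exp(-tc / tau_r)
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_r)
    return np.where(t >= 0, raw / peak, 0.0)


def _lognormal_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given coefficient of variation."""
    if cv == 0:
        return np.ones(n)
    s2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=n)


# ---------------------------------------------------------------------------
# Trial schedules
# ---------------------------------------------------------------------------

def gen_trial_events(
    layout: TrialLayout, n_trials: int, rng: np.random.Generator
) -> tuple[EventStream, np.ndarray]:
    """Draw trial start times and expand the layout into an EventStream.

    Returns the events plus the per-event 1-based trial numbers.  Events
    with a delivery probability in ``layout.us_probability`` are dropped
    (Bernoulli) on omission trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    gaps = rng.uniform(layout.iti[0], layout.iti[1], size=n_trials)
    gaps[0] = 0.0
    starts = layout.lead_in + np.cumsum(gaps + layout.span) - layout.span
    onsets, labels, durations, trial_no = [], [], [], []
    for i, s in enumerate(starts):
        for off, lab, dur in layout.events:
            if lab in layout.us_probability and rng.random() >= layout.us_probability[lab]:
                continue
            onsets.append(s + off)
            labels.append(lab)
            durations.append(dur)
            trial_no.append(i + 1)
    order = np.argsort(np.asarray(onsets), kind="stable")
    ev = EventStream(
        np.asarray(onsets)[order],
        np.asarray(labels, dtype=object)[order],
        np.asarray(durations)[order],
    )
    return ev, np.asarray(trial_no)[order]


# ---------------------------------------------------------------------------
# Photometry generators
# ---------------------------------------------------------------------------

def _render_trace(
    times: np.ndarray,
    events: EventStream,
    trial_no: np.ndarray,
    components: tuple[KernelComponent, ...],
    *,
    amplitude_cv: float,
    noise_sd: float,
    drift_tau: float,
    schedule: LearningSchedule | None,
    rng: np.random.Generator,
    rate: float,
) -> np.ndarray:
    n = times.size
    signal = np.zeros(n)
    for comp in components:
        mask = events.labels == comp.label
        if not np.any(mask):
            continue
        onsets = events.onsets[mask] + comp.offset
        trials = trial_no[mask]
        amps = comp.amplitude * _lognormal_factors(rng, onsets.size, amplitude_cv)
        if comp.learned and schedule is not None:
            amps = amps * schedule.gain(trials)
        support = min(10.0 * comp.tau_decay + comp.t_peak, 80.0)
        n_sup = int(round(support * rate))
        rel_t = np.arange(n_sup) / rate
        kern = transient_kernel(rel_t, comp.t_peak, comp.tau_decay)
        for onset, amp in zip(onsets, amps):
            i0 = int(round(onset * rate))
            i1 = min(i0 + n_sup, n)
            if i0 < n:
                signal[i0:i1] += amp * kern[: i1 - i0]
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=n)
    drift = np.exp(-times / drift_tau) if drift_tau > 0 else 1.0
    return drift * (1.0 + signal)


def gen_photometry_session(
    preset: TransientPreset,
    n_trials: int,
    layout: TrialLayout,
    schedule: LearningSchedule | None = None,
    seed: int | None = None,
    *,
    cue_amplitude: float | None = None,
    rate: float = PHOTOMETRY_RATE,
) -> tuple[Recording, EventStream]:
    """Simulate a photometry session for a single-transient preset.

    Non-cue events carry the preset transient; ``cue``-labeled events carry
    a kernel of the same shape with peak amplitude ``cue_amplitude``
    (default: the preset amplitude), scaled per trial by ``schedule.gain``
    and signed by its direction.  The trace is
    ``B(t) (1 + signal + noise)`` with ``B`` the photobleaching drift.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _rng(seed)
    events, trial_no = gen_trial_events(layout, n_trials, rng)
    components = []
    for lab in dict.fromkeys(events.labels):  # preserve first-seen order
        if lab == "cue":
            amp = preset.amplitude if cue_amplitude is None else cue_amplitude
            if schedule is not None:
                amp *= schedule.sign
            components.append(
                KernelComponent("cue", amp, preset.t_peak, preset.tau_decay, learned=True)
            )
        else:
            components.append(
                KernelComponent(lab, preset.amplitude, preset.t_peak, preset.tau_decay)
            )
    duration = events.onsets[-1] + events.durations[-1] + layout.tail
    times = np.arange(int(round(duration * rate))) / rate
    trace = _render_trace(
        times,
        events,
        trial_no,
        tuple(components),
        amplitude_cv=preset.amplitude_cv,
        noise_sd=preset.noise_sd,
        drift_tau=preset.drift_tau,
        schedule=schedule,
        rng=rng,
        rate=rate,
    )
    return Recording(trace, rate, 0.0, "gcamp"), events


def gen_photometry_site(
    components: tuple[KernelComponent, ...],
    n_trials: int,
    layout: TrialLayout,
    schedule: LearningSchedule | None = None,
    seed: int | None = None,
    *,
    amplitude_cv: float = 0.3,
    noise_sd: float = 0.01,
    drift_tau: float = 2000.0,
    rate: float = PHOTOMETRY_RATE,
) -> tuple[Recording, EventStream]:
    """Simulate a recording site whose profile is a sum of signed components."""
    rng = _rng(seed)
    events, trial_no = gen_trial_events(layout, n_trials, rng)
    duration = events.onsets[-1] + events.durations[-1] + layout.tail
    times = np.arange(int(round(duration * rate))) / rate
    trace = _render_trace(
        times,
        events,
        trial_no,
        components,
        amplitude_cv=amplitude_cv,
        noise_sd=noise_sd,
        drift_tau=drift_tau,
        schedule=schedule,
        rng=rng,
        rate=rate,
    )
    return Recording(trace, rate, 0.0, "gcamp"), events


# ---------------------------------------------------------------------------
# Spike generators
# ---------------------------------------------------------------------------

def spike_rate_function(
    t: np.ndarray, cue_onsets: np.ndarray, preset: SpikeProfilePreset
) -> np.ndarray:
    """Instantaneous firing rate (spikes/s) at absolute times ``t``.

    Relative to each cue onset: ``cue_rate`` over [0, 4) s (cue + delay),
    ``us_rate`` over [4, 5) s (sucrose delivery and immediate aftermath),
    then an exponential relaxation from ``rebound_rate`` back to baseline —
    a rebound above baseline for type2, a sub-baseline recovery for type1.
    """
    t = np.asarray(t, dtype=float)
    cue_onsets = np.asarray(cue_onsets, dtype=float)
    if cue_onsets.size == 0:
        return np.full(t.shape, preset.baseline_rate)
    idx = np.searchsorted(cue_onsets, t, side="right") - 1
    rel = np.where(idx >= 0, t - cue_onsets[np.clip(idx, 0, None)], -1.0)
    rate = np.full(t.shape, preset.baseline_rate)
    rate = np.where((rel >= 0) & (rel < 4.0), preset.cue_rate, rate)
    rate = np.where((rel >= 4.0) & (rel < 5.0), preset.us_rate, rate)
    post = rel >= 5.0
    rate = np.where(
        post,
        preset.baseline_rate
        + (preset.rebound_rate - preset.baseline_rate)
        * np.exp(-(np.clip(rel, 5.0, None) - 5.0) / preset.rebound_tau),
        rate,
    )
    return rate


def _spike_waveform(rng: np.random.Generator, n_channels: int = 4, n_samples: int = 32) -> np.ndarray:
    """Biphasic extracellular waveform template, per-channel amplitudes in µV."""
    x = np.arange(n_samples)
    t0, w = 8.0, 2.5
    shape = -np.exp(-((x - t0) ** 2) / (2 * w**2)) + 0.45 * np.exp(
        -((x - t0 - 6) ** 2) / (2 * (2 * w) ** 2)
    )
    amps = rng.uniform(40.0, 120.0, size=n_channels)
    return amps[:, None] * shape[None, :]


def gen_spike_unit(
    preset: SpikeProfilePreset,
    n_trials: int,
    layout: TrialLayout,
    seed: int | None = None,
    *,
    unit_id: str = "u0",
    events: EventStream | None = None,
) -> tuple[SpikeUnit, EventStream]:
    """Inhomogeneous-Poisson unit following the preset rate profile.

    Spikes are drawn by thinning a homogeneous Poisson process at the
    profile's maximum rate.  Pass ``events`` to reuse a shared trial
    schedule (population generation); otherwise one is drawn from the seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if events is None:
        events, _ = gen_trial_events(layout, n_trials, rng)
    cue_onsets = events.select("cue").onsets if "cue" in events.vocabulary else events.onsets
    duration = float(events.onsets[-1] + events.durations[-1] + layout.tail)
    rate_max = max(preset.baseline_rate, preset.cue_rate, preset.us_rate, preset.rebound_rate)
    if rate_max == 0:
        spikes = np.empty(0)
    else:
        n_cand = rng.poisson(rate_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        accept = rng.random(n_cand) < spike_rate_function(cand, cue_onsets, preset) / rate_max
        spikes = np.unique(cand[accept])
    unit = SpikeUnit(
        spikes,
        _spike_waveform(rng),
        unit_id=unit_id,
        t_start=0.0,
        t_stop=duration,
    )
    return unit, events


def gen_tagging_epoch(preset: TaggingPreset, seed: int | None = None) -> SpikeUnit:
    """Spontaneous Poisson spiking plus light-evoked spikes for tagging.

    The pulse train (``n_pulses`` at ``pulse_rate``) is placed after a
    stimulation-free epoch at least 10x the train's span, as the bootstrap
    null requires.  Each pulse evokes one spike with probability
    ``reliability`` at ``latency_mean`` + Gaussian jitter (truncated > 0).
    The evoked mean waveform equals the spontaneous one up to a small
    perturbation.
    """
    rng = _rng(seed)
    span = preset.n_pulses / preset.pulse_rate
    pre = max(10.0 * span, 60.0) + 5.0
    pulses = pre + np.arange(preset.n_pulses) / preset.pulse_rate
    total = pre + span + 5.0
    n_spont = rng.poisson(preset.spont_rate * total)
    spont = rng.uniform(0.0, total, size=n_spont)
    hit = rng.random(preset.n_pulses) < preset.reliability
    lat = preset.latency_mean + preset.latency_jitter * rng.standard_normal(preset.n_pulses)
    lat = np.clip(lat, 2.5e-4, None)
    evoked = (pulses + lat)[hit]
    spikes = np.unique(np.concatenate([spont, evoked]))
    wf = _spike_waveform(rng)
    pert = preset.waveform_perturbation * np.std(wf) * rng.standard_normal(wf.shape)
    unit = SpikeUnit(
        spikes,
        wf,
        unit_id="tagged",
        light_pulses=pulses,
        pulse_width=preset.pulse_width,
        t_start=0.0,
        t_stop=total,
        waveform_evoked=wf + pert,
    )
    return unit


def gen_population(spec: MixtureSpec) -> tuple[list[SpikeUnit], EventStream, list[str]]:
    """Independent units sharing one trial schedule.

    Returns (units, shared events, per-unit profile names).  Per-unit seeds
    are keyed by unit index, so permuting generation order cannot change
    any unit's data.
    """
    sched_rng = _rng(spec.seed, 0)
    events, _ = gen_trial_events(spec.layout, spec.n_trials, sched_rng)
    units, names = [], []
    for i, name in enumerate(spec.members):
        preset = SPIKE_PRESETS[name] if isinstance(name, str) else name
        unit, _ = gen_spike_unit(
            preset,
            spec.n_trials,
            spec.layout,
            seed=_rng(spec.seed, i + 1),
            unit_id=f"u{i}",
            events=events,
        )
        units.append(unit)
        names.append(name)
    return units, events, names


def gen_photometry_population(
    spec: MixtureSpec,
    schedule: LearningSchedule | None = APPETITIVE_SCHEDULE,
) -> tuple[list[Recording], EventStream, list[str]]:
    """Photometry recording sites sharing one trial schedule.

    Mixture count keys must name :data:`SITE_PRESETS` entries
    (``site_type1`` / ``site_type2``).
    """
    sched_rng = _rng(spec.seed, 0)
    events, trial_no = gen_trial_events(spec.layout, spec.n_trials, sched_rng)
    duration = float(events.onsets[-1] + events.durations[-1] + spec.layout.tail)
    rate = PHOTOMETRY_RATE
    times = np.arange(int(round(duration * rate))) / rate
    recs, names = [], []
    for i, name in enumerate(spec.members):
        comp = SITE_PRESETS[name] if isinstance(name, str) else name
        trace = _render_trace(
            times,
            events,
            trial_no,
            comp,
            amplitude_cv=0.3,
            noise_sd=0.01,
            drift_tau=2000.0,
            schedule=schedule,
            rng=_rng(spec.seed, i + 1),
            rate=rate,
        )
        recs.append(Recording(trace, rate, 0.0, f"site{i}"))
        names.append(name)
    return recs, events, names


# ---------------------------------------------------------------------------
# Locomotion
# ---------------------------------------------------------------------------

def gen_locomotion(
    events: EventStream,
    suppression_schedule: LearningSchedule | None = None,
    seed: int | None = None,
    *,
    rate: float = 25.0,
    base_speed: float = 8.0,
    depth: float = 0.8,
    window: tuple[float, float] = (0.0, 4.0),
    duration: float | None = None,
) -> PositionTrace:
    """Random-walk positions whose post-cue step size follows a schedule.

    Within ``window`` after each cue onset the step size is multiplied by
    ``1 - depth * gain(trial)``: locomotor suppression that deepens as
    conditioning proceeds.  ``base_speed`` is the mean unsuppressed speed
    (cm/s) of the 2-D Gaussian walk.
    """
    rng = _rng(seed)
    cues = events.select("cue").onsets if "cue" in events.vocabulary else events.onsets
    if duration is None:
        duration = float(events.onsets[-1] + events.durations[-1] + 15.0)
    times = np.arange(int(round(duration * rate))) / rate
    mult = np.ones(times.size)
    if suppression_schedule is not None:
        gains = suppression_schedule.gain(np.arange(1, cues.size + 1))
        idx = np.searchsorted(cues, times, side="right") - 1
        rel = np.where(idx >= 0, times - cues[np.clip(idx, 0, None)], -1.0)
        in_win = (rel >= window[0]) & (rel < window[1])
        mult = np.where(in_win, 1.0 - depth * np.asarray(gains)[np.clip(idx, 0, None)], 1.0)
    sigma = base_speed / (rate * math.sqrt(math.pi / 2.0))
    steps = rng.standard_normal((times.size, 2)) * (sigma * mult)[:, None]
    steps[0] = 0.0
    xy = np.cumsum(steps, axis=0)
    return PositionTrace(times, xy)


def preset_with(preset: TransientPreset, **kw) -> TransientPreset:
    """Convenience: a copy of ``preset`` with fields replaced."""
    return replace(preset, **kw)
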