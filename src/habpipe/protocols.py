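"""Canonical simulation + analysis protocols at the study's conditions.

Each function wires the synthetic generators to the analysis pipeline the
way the corresponding experiment was run — group transient recovery over
mice, family-wise error calibration of the max-|T| test, population
baseline firing, ensemble clustering, null ROC profiles, and tagging
calibration — and returns the summary numbers.  They are used by the
verification suite, the acceptance script, and the numbered analysis
drivers, so every reported quantity comes from one code path.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` sub-streams.
"""

from __future__ import annotations

import numpy as np

from . import synthetic_data as sd
from .optotag import tag_unit
from .perm_stats import maxt_test
from .photometry_erf import (
    ALIGN_WINDOW,
    BASELINE_WINDOW,
    SOCIAL_BASELINE_WINDOW,
    ERFMatrix,
    compute_dff,
    response_metrics,
    smooth_trace,
    zscore_erf,
)
from .response_clustering import assign_type, cluster_profiles
from .roc_selectivity import sliding_roc
from .spike_peth import gaussian_smooth, peth, zscore_profile

__all__ = [
    "GROUP_SIZES",
    "transient_recovery",
    "null_erf",
    "fwer_calibration",
    "population_baseline_rate",
    "spike_cluster_type1_size",
    "photometry_cluster_type1_size",
    "null_roc_mean_auc",
    "tagging_calibration",
]

#: Mice per photometry test group (quinine / footshock / social attack).
GROUP_SIZES = {"quinine": 7, "footshock": 8, "social": 7}


def _child_seed(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _child_int(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0] % (2**31))


def transient_recovery(
    preset_name: str,
    seed: int,
    n_sessions: int | None = None,
    n_trials: int = 10,
) -> dict[str, float]:
    """Group-mean transient metrics recovered from synthetic sessions.

    Simulates ``n_sessions`` animals (default: the study group size) of
    ``n_trials`` stimulus deliveries each with the named preset, runs the
    dF/F pipeline per session, and averages peak, time-to-peak and decay
    tau of the session-mean ERFs.
    """
    preset = sd.TRANSIENT_PRESETS[preset_name]
    layout = sd.LAYOUTS[preset_name]
    baseline = SOCIAL_BASELINE_WINDOW if preset_name == "social" else BASELINE_WINDOW
    if n_sessions is None:
        n_sessions = GROUP_SIZES[preset_name]
    peaks, tps, taus = [], [], []
    for i in range(n_sessions):
        rec, ev = sd.gen_photometry_session(
            preset, n_trials, layout, seed=_child_int(seed, 1, i)
        )
        m = compute_dff(smooth_trace(rec), ev, baseline, ALIGN_WINDOW)
        met = response_metrics(m, (0.0, ALIGN_WINDOW[1]))
        peaks.append(met.peak_dff)
        tps.append(met.t_peak)
        taus.append(met.tau_decay)
    return {
        "peak_dff": float(np.mean(peaks)),
        "t_peak_s": float(np.mean(tps)),
        "tau_decay_s": float(np.mean(taus)),
        "n_sessions": n_sessions,
    }


def null_erf(
    rng: np.random.Generator,
    n_trials: int = 10,
    window: tuple[float, float] = ALIGN_WINDOW,
    rate: float = 500.0,
    noise_sd: float = 0.01,
) -> ERFMatrix:
    """Signal-free trial matrix: i.i.d. Gaussian noise on the ERF grid."""
    n_t = int(round((window[1] - window[0]) * rate))
    axis = window[0] + np.arange(n_t) / rate
    return ERFMatrix(rng.normal(0.0, noise_sd, size=(n_trials, n_t)), axis)


def fwer_calibration(
    seed: int,
    n_runs: int = 1000,
    n_trials: int = 10,
    n_perm: int = 1000,
    alpha: float = 0.05,
    n_timepoints: int | None = None,
) -> float:
    """Family-wise false-positive rate of the max-|T| test on null data.

    Fraction of independent signal-free runs (12 s of 500 Hz samples per
    trial by default) in which the test reports any significant segment.
    ``n_timepoints`` shortens each trial for reduced-scale runs.
    """
    hits = 0
    for i in range(n_runs):
        rng = _child_seed(seed, 2, i)
        m = null_erf(rng, n_trials=n_trials)
        if n_timepoints is not None:
            m = ERFMatrix(m.values[:, :n_timepoints], m.time_axis[:n_timepoints])
        res = maxt_test(
            m, BASELINE_WINDOW, n_perm=n_perm, alpha=alpha, seed=_child_int(seed, 3, i)
        )
        hits += bool(res.segments_up or res.segments_down)
    return hits / n_runs


def _population_zprofiles(
    spec: sd.MixtureSpec,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Smoothed, z-scored cue-aligned PETH profiles for a spike ensemble."""
    units, ev, names = sd.gen_population(spec)
    profiles, baselines = [], []
    axis = None
    for u in units:
        p = gaussian_smooth(peth(u, ev, label="cue"))
        axis = p.time_axis
        baselines.append(float(p.window_means((-2.0, 0.0)).mean()))
        profiles.append(zscore_profile(p).z)
    return np.asarray(profiles), axis, names, np.asarray(baselines)


def population_baseline_rate(seed: int, n_units: int = 70, n_trials: int = 100) -> float:
    """Mean pre-cue ([-2, 0] s) PETH firing rate across a synthetic ensemble.

    The ensemble uses the recorded mixture composition (37 pure-inhibition,
    33 rebounding out of 70) and the ~30 spikes/s baseline preset.
    """
    n1 = round(n_units * 37 / 70)
    spec = sd.MixtureSpec(
        {"sucrose_type1": n1, "sucrose_type2": n_units - n1},
        n_trials=n_trials,
        seed=_child_int(seed, 4),
    )
    _, _, _, baselines = _population_zprofiles(spec)
    return float(baselines.mean())


def spike_cluster_type1_size(seed: int, n_trials: int = 100) -> int:
    """Size of the pure-inhibition cluster for a 37+33 synthetic ensemble."""
    spec = sd.MixtureSpec(
        {"sucrose_type1": 37, "sucrose_type2": 33}, n_trials=n_trials, seed=_child_int(seed, 5)
    )
    profiles, axis, _, _ = _population_zprofiles(spec)
    model = cluster_profiles(profiles, axis)
    types = assign_type(model)
    return int(np.sum(types == "typeI"))


def photometry_cluster_type1_size(seed: int, n_trials: int = 100) -> int:
    """Pure-inhibition cluster size for a 9+9 synthetic recording-site ensemble."""
    spec = sd.MixtureSpec(
        {"site_type1": 9, "site_type2": 9}, n_trials=n_trials, seed=_child_int(seed, 6)
    )
    recs, ev, _ = sd.gen_photometry_population(spec)
    profiles = []
    axis = None
    for rec in recs:
        m = compute_dff(smooth_trace(rec), ev, BASELINE_WINDOW, ALIGN_WINDOW, label="cue")
        axis = m.time_axis
        profiles.append(zscore_erf(m, BASELINE_WINDOW))
    model = cluster_profiles(np.asarray(profiles), axis)
    types = assign_type(model)
    return int(np.sum(types == "typeI"))


def null_roc_mean_auc(seed: int, n_runs: int = 100, n_trials: int = 10) -> float:
    """Mean sliding-window AUC over signal-free ERF matrices (expect 0.5)."""
    means = []
    for i in range(n_runs):
        m = null_erf(_child_seed(seed, 7, i), n_trials=n_trials)
        prof = sliding_roc(m, n_perm=0)
        means.append(prof.mean_auc)
    return float(np.mean(means))


def tagging_calibration(
    seed: int, n_null: int = 200, n_boot: int = 1000
) -> dict[str, float]:
    """Tagging decisions for one locked unit and ``n_null`` unmodulated units.

    Returns the locked unit's C, R and bootstrap p plus the number of null
    (reliability-0) units crossing the strict c > 0.85, p < 0.001 criteria.
    """
    locked = sd.gen_tagging_epoch(sd.TaggingPreset(), seed=_child_int(seed, 8))
    res = tag_unit(locked, n_boot=n_boot, seed=_child_int(seed, 9))
    false_tags = 0
    for i in range(n_null):
        u = sd.gen_tagging_epoch(
            sd.TaggingPreset(reliability=0.0), seed=_child_int(seed, 10, i)
        )
        null_res = tag_unit(u, n_boot=n_boot, seed=_child_int(seed, 11, i))
        false_tags += int(null_res.tagged)
    return {
        "locked_c": res.c,
        "locked_r": res.r,
        "locked_p": res.p,
        "locked_tagged": float(res.tagged),
        "false_tags": float(false_tags),
        "n_null": float(n_null),
    }
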