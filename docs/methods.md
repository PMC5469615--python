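# Methods

habpipe analyzes trial-aligned neural recordings of the kind produced by
fiber photometry (a bulk Ca2+ fluorescence trace per site, digitized at
500 Hz) and extracellular tetrode recordings (sorted single-unit spike
trains with optogenetic tagging pulses), acquired while an animal
experiences aversive or rewarding events.  This note documents the models,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic test bed does and does not establish.

## Event-related fluorescence (ERF)

Raw fluorescence is smoothed with a centered 20 ms moving average
(shrunken windows at the edges, so length and constants are preserved),
segmented around event onsets, and converted to fractional change

    dF/F(t) = (F(t) - F0) / F0,

where `F0` is the mean smoothed fluorescence over a per-trial control
window.  The default control window is **[-2.0, -0.5] s**: 1.5 s long,
ending 0.5 s before onset.  The "0.5 s" figure is read as the *gap*
between the window and the event, not the window length; this is
ambiguous in the protocol it follows and is therefore a configurable
parameter (`baseline_window`).  Social-interaction analyses move the
window to end 3.5 s before interaction onset ([-5.0, -3.5] s) so that
chasing immediately before an attack does not contaminate the baseline.
`F0` is per-trial rather than session-wide so slow drift cancels.

Per-trial baselines make dF/F exactly invariant to rescaling the raw
trace by any positive constant, and alignment is invariant to a common
time shift of trace and events; both are enforced by property tests.

Response metrics are computed on the trial-averaged ERF within a response
window (default 0–10 s): the peak dF/F, the time from onset to that peak,
the AUC (sum of dF/F samples over a named window — window presets 0–2 s
cue, 4.0–4.5 s US, 5–10 s post-reward), and a decay constant from a
least-squares mono-exponential `A exp(-t/tau)` fitted from the peak to
the window end (trust-region solver, `tau` seeded at the 1/e crossing, a
non-positive peak skips the fit and flags the result).  On a noiseless
difference-of-exponentials transient this fit recovers the decay constant
to better than 1% despite the residual rise component near the peak.

## Max-|T| multivariate permutation test

To decide where a trial-averaged response differs from baseline without
inflating the error rate across thousands of timepoints, the pipeline
uses a maximum-statistic permutation test: subtract each trial's
control-window mean, form the one-sample t-statistic across trials at
every timepoint, and build the null by randomly sign-flipping whole
baseline-subtracted trial traces (1000 permutations, alpha 0.05 default),
recording the maximum |T| over time for each flip.  Pointwise p-values
are the add-one-corrected rank of |T(t)| in that max-null, which controls
the family-wise error rate in two-tailed tests; maximal runs of p < alpha
are reported as increase/decrease segments.

Design choices:

* **Sign flipping** (not time shuffling) is the exchangeability scheme:
  it preserves within-trial autocorrelation and matches the paired,
  against-baseline design.  Trial-level exchange is the default; group
  analyses can pre-average per animal and permute at that level.
* **Ties count as exceeding** (`|T*| >= |T|`), which is conservative, and
  the add-one convention keeps p >= 1/(n_perm+1).
* With `exhaustive=True` all `2^n` sign assignments are enumerated and
  p-values are exact; the test suite verifies exact agreement with an
  independent brute-force enumeration at n = 4–5.
* Because the per-timepoint sum of squares is invariant under sign flips,
  the whole null distribution reduces to one signs-by-data matrix product
  — a 10-trial x 6000-timepoint test with 1000 permutations runs in
  ~0.1 s, which is what makes the 1000-run false-positive calibration
  practical.

The same machinery covers PETH matrices.  Scalar response strength and
selectivity comparisons use a two-sample label-shuffling permutation test
on the difference of means (exhaustively enumerated whenever the number
of splits is at most 4096), and distribution comparisons use the
two-sample Kolmogorov–Smirnov test (scipy, asymptotic p).

## Sliding-window ROC

Activation/inhibition profiles compare the per-trial mean dF/F in a
200 ms test window (advanced in 50 ms steps; windows that would overrun
the axis are dropped) with the per-trial mean in a fixed 200 ms control
window 1.8 s before onset ([-2.0, -1.8] s).  The AUC is
`P(test > control) + 0.5 P(test = control)`, computed by midranks
(Mann–Whitney U / n_a n_b) and verified against ordered-pair enumeration;
0.5 means no discrimination, >0.5 activation, <0.5 inhibition.  The
per-trial summary is the *mean over samples in the window*: pooling raw
samples across trials was rejected because samples within a trial are not
exchangeable.  Between-condition selectivity uses the same windows with
the two conditions' per-trial means (1 = fully condition-1-selective);
raw window means are compared without re-baselining.  Window p-values
come from label-shuffling permutations; passing `n_perm=0` skips them.

## Peri-event time histograms and standard scores

Spike counts are binned at 50 ms around event onsets and divided by the
bin width (counts are conserved exactly before smoothing), then smoothed
per trial with a normalized Gaussian kernel, sigma = 50 ms, truncated at
±4 sigma with reflected edges (preserves mass near boundaries).  Standard
scores standardize the trial-averaged rate against a control period,
default the 2 s before cue onset: `z = (rate - mu_ctrl) / sd_ctrl`.  The
dispersion is computed **across the control bins of the trial-averaged
profile** (not across trials); a profile whose control bins are exactly
constant has undefined z and is flagged rather than repaired.

## Optogenetic tagging

A unit is accepted as optogenetically identified when both hold
(strict inequalities):

* waveform correlation `C > 0.85` — Pearson correlation of the
  concatenated per-channel mean waveforms of spontaneous vs light-evoked
  spikes;
* bootstrap `p < 0.001` for light-locked firing.

Per 5 ms pulse (10 Hz trains) the first spike within 10 ms of onset
defines the latency; reliability `R` is the fraction of pulses with such
a spike.  The null places surrogate trains — same pulse count and 10 Hz
spacing, shifted rigidly — uniformly in the stimulation-free epochs of
the recording (required: total free duration at least 10x the train
span), recomputing the statistic per surrogate;
`p = (1 + #{surrogate >= observed}) / (n_boot + 1)`.  The default
statistic is `R` itself, which stays well-defined at low spontaneous
rates; a median-latency variant (`statistic="median_latency"`) is
provided because the exact prior-art statistic is not fully specified.
Rigid shifts (rather than independent pulse placement) preserve
within-train dependence of spontaneous spiking under the null.

Note a structural property of the decision rule: with n_boot = 1000 the
smallest attainable p is 1/1001 = 0.000999 < 0.001, so an unmodulated
unit is falsely tagged with probability at most ~1/1001 (ties make it
rarer).  The calibration test checks the binomial envelope of that
nominal rate over 200 null units.

## Type I / Type II response clustering

Standardized response profiles (units x timepoints of z-scores) are
mean-centered per timepoint and projected onto the first three principal
components; pairwise Euclidean distances between score vectors feed
complete-linkage agglomeration, cut at k = 2.  Profiles are *not*
re-scaled per timepoint before PCA — they are already standard scores,
and double-scaling would distort between-unit geometry.  Clusters are
relabeled in descending order of their mean-profile total Z over the
5–10 s post-cue window, so cluster 1 is the rebound ("inhibition-then-
excitation", Type II) group and the other is pure inhibition (Type I);
"minor adjustments" are label ordering only, never reassignment.  Ties in
the ordering statistic break deterministically by cluster size, with a
logged warning.  The procedure has no randomness and is input-order
invariant; rank-deficient inputs fall back to the available components
with a flag.  A fixed k = 2 is the default because two major profile
types is the phenomenon of interest; the dendrogram is exported
(Newick text) for other cuts.

## Synthetic data generator

The generator produces sessions with the statistical structure of the
recordings so that every stage has a ground truth.

**Ca2+ transient kernel.**  A difference of exponentials
`k(t) = c (exp(-t/tau_d) - exp(-t/tau_r))` with `tau_r` solved
numerically (Brent) so the peak sits at `t_peak`, and `c` normalizing the
peak to 1.  Only time-to-peak and decay constant are reported for the
real transients, and this is the minimal kernel matching both.  Built-in
presets (peak dF/F, t_peak s, tau_d s): quinine (0.278, 0.68, 5.88),
footshock (0.488, 0.26, 1.89), social attack (0.329, 0.57, 7.80).

**Trace model.**  `F(t) = B(t) (1 + sum_i a_i k(t - t_i) + eps)` with
photobleaching drift `B(t) = exp(-t/drift_tau)` and i.i.d. Gaussian
sample noise `eps`.  Transients are multiplicative on the drift because
bleaching attenuates transient fluorescence along with the baseline;
this keeps the dF/F amplitude recovered against a local baseline equal
to the preset amplitude regardless of session length.  Unreported
quantities were fixed once at realistic values and exposed as
parameters: trial amplitudes are lognormal with CV 0.3 (strictly
positive, moderate trial-to-trial variability), noise_sd 0.01 dF/F at
500 Hz (consistent with a low-power, 40 Hz-low-passed photometry chain),
drift_tau 2000 s (slow bleaching at 0.03–0.04 mW excitation, enough to
exercise the per-trial baseline).

**Trial layouts** follow the behavioral protocols: 0.5 s infusions with
inter-trial intervals uniform in 110–130 s (quinine) or 20–40 s
(sucrose/footshock); conditioning trials are a 2 s tone, 2 s delay, and a
0.5 s US; a probabilistic-reward layout delivers the US with per-cue
Bernoulli probability (75%/25% preset).  Learning is a logistic per-trial
gain on cue-locked components, `g(n) = 1/(1+exp(-k(n-h)))`, ~0 on trial
1 and saturating at 1: aversive default h = 7, k = 0.8 (responses emerge
within 5–10 trials); appetitive default h = 135, k = 0.05 (significant
after ~120–150 trials).  A two-parameter monotone family is the simplest
curve consistent with the reported onset ranges and is recoverable from
blockwise tests.

**Spike profiles.**  Inhomogeneous Poisson trains drawn by thinning at
the profile maximum.  Relative to each cue onset: baseline 30 spikes/s,
25 during cue+delay (0–4 s), 20 during reward delivery and its immediate
aftermath (4–5 s), then exponential relaxation to baseline from
`rebound_rate` with time constant `rebound_tau` — above baseline
(default 45 spikes/s, tau 1.5 s) for Type II units, a sub-baseline
recovery for Type I.  The Type II rebound excess (~15 spikes/s) is large
against the profile noise of a 100-trial PETH (~1 spike/s), matching the
clearly separable types in the recordings.

**Tagging epochs.**  Spontaneous Poisson spiking plus one evoked spike
per pulse with probability `reliability` at `latency_mean` (3 ms) with
Gaussian jitter (1 ms, truncated positive); 600 pulses at 10 Hz placed
after a stimulation-free epoch >= 10x the train span.  The evoked mean
waveform equals the spontaneous one plus 5% perturbation.  Note the
*measured* reliability exceeds the evoked probability slightly because a
spontaneous spike can also land in the 10 ms window:
`E[R_hat] = R + (1-R)(1 - exp(-lambda w))`, which the tests use.

**Populations** share one trial schedule; per-unit RNG streams are keyed
by (master seed, unit index), so generation order cannot change any
unit's data.  Default mixtures mirror the recorded ensembles: 37 Type I +
33 Type II units, and 9 + 9 photometry sites (site profiles are signed
kernel components: learned cue dip, reward dip, and for Type II a
rebound locked to reward offset).

**Locomotion** is a 2-D Gaussian random walk (mean speed 8 cm/s at
25 Hz tracking) whose step size within the 0–4 s post-cue window is
multiplied by `1 - depth * gain(trial)` — conditioned suppression that
deepens with learning.

Every generator is byte-deterministic under a fixed seed.

### What the generator does not emulate

Motion and hemodynamic artifacts, isosbestic control channels, fiber
autofluorescence, biophysical GCaMP kinetics (the kernel is
phenomenological), non-Poisson spike-train structure (refractoriness,
bursting), spike-sorting contamination, electrical artifacts of light
pulses, and across-animal heterogeneity beyond independent seeds.
Passing tests therefore establish that the pipeline recovers known
parameters and holds its error rates under the stated noise model — not
that it is robust to artifacts absent from that model.

## Verification problem sizes

The test suite runs the full protocols at the study's scale where that is
cheap (7–8 sessions x 10 trials; 70 units x 100 trials; 20-seed ensemble
replications) and at reduced scale for the heaviest calibrations (200
null sessions x 200 permutations for the family-wise error rate; the
acceptance script runs the full 1000 x 1000).  All reduced scales keep
the binomial margins they are tested against.

## Known limitations

* The mono-exponential tau fit is slightly biased by the rise component
  just after the peak (well under the reported between-animal spread).
* `learning_onset` requires the significance flag to hold through the
  final block; late noise flips return a later onset rather than an
  uncertainty interval.
* The bootstrap tagging p cannot go below 1/(n_boot+1); with the strict
  p < 0.001 criterion, n_boot must exceed 1000 for the criterion to be
  attainable at all, and borderline units should be re-run at larger
  n_boot.
* Complete-linkage with k fixed at 2 will split a genuinely unimodal
  population; the exported dendrogram should be inspected when the
  ordering statistics of the two clusters are close.
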