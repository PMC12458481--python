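# Methods

## The task and what the generator emulates

A session alternates "cued" and "self-paced" blocks, starting cued, with
block transitions after a fixed number of rewards (default 3 block pairs of
30 rewards).  In cued blocks a trial is: inter-trial interval uniform on
4–8 s, a pre-cue hold of 1.5–2.5 s, a go cue, and a rewarded press if the
5 mm lever threshold is crossed within 2 s of the cue.  Reaction times are
drawn from an exponential with mean 0.30 s truncated at the 2 s window
(inverse-CDF truncation, so every cued trial is rewarded; the truncated mean
is 0.2975 s).  In self-paced blocks the ITI is 2–3 s and the rewarded press
occurs an exponential (mean 6.0 s) after trial start; the task's 1–2 s
"quiet period" is honoured by keeping unrewarded presses out of the
pre-press window rather than by delaying the press draw, so the configured
mean reaction time is exact.  Unrewarded ITI presses arrive at a Poisson
rate of 1 per trial, putting the rewarded fraction near 0.5.  Every press
deposits the same half-sine lever template (8 mm, 0.4 s), positioned so the
5 mm up-crossing falls exactly at the press time; context differences in
lever kinematics are deliberately absent.

Neural ground truth: each neuron is an archetype — *action* (transient at
every press, both contexts), *cue* (cue onsets only) or *post_action*
(reward-triggered, peaking ~1 s later) — with a peak-normalised
difference-of-exponentials calcium kernel (rise 0.05 s, decay 0.5 s; the
kernel peaks 0.128 s after its trigger).  Optional planted structure:

* **context gain** g: action/post-action responses in cued blocks scaled by
  g^s, s = ±1 per neuron, so the population mean stays balanced while
  context is decodable;
* **divergence bump**: a Gaussian (amplitude in ΔF/F fraction, centre
  relative to the press, width σ) added to press-aligned activity with
  opposite sign in the two contexts and a random ± per neuron — a
  time-localised, population-mean-zero context signal.  Its window
  (centre ± 2σ) is recorded in the ground truth;
* **context-only cells** (`context_cells_fraction`): a sub-population with
  no archetype response that carries only the bump, giving exactly disjoint
  context and action supports;
* **cell-type structure**: D1-labelled cue cells carry an early cue boost,
  D2-labelled cells a boosted slow late component (peak ~1.5 s), matching
  the direction of the reported pathway differences.

Raw traces are Suite2p-like: `raw = F0·(1+signal) + drift + 0.7·neuropil +
noise`, with the neuropil trace carrying a smoothed shared population signal
plus its own noise, slow sinusoid-plus-ramp drift, and white noise.  One
master seed spawns separate sub-streams for behaviour, population structure
and noise, so e.g. the same population can be re-rendered with different
noise.

What the generator does *not* emulate — and hence what passing tests do not
establish about real recordings: spike-to-calcium nonlinearity and indicator
saturation; correlated (shared-latent) noise across neurons; motion
artifacts and slow photobleaching beyond the planted drift; licking and
other uninstructed movements; any genuine preparatory ramping (all archetype
kernels are causal, so pre-press decodability must come from cue responses
or planted bumps, never from "intention" signals).

## Preprocessing

Per ROI: neuropil correction (coefficient 0.7), Gaussian smoothing, a
50th-percentile filter in non-overlapping 60 s windows (a final partial
window gets its own percentile), expansion to full length by linear
interpolation between window centres with constant ends (a piecewise-constant
mode is available), percent ΔF/F, session-wide z-score.  ROIs whose baseline
reaches zero or below, or whose corrected trace has no variance, are
excluded with a per-ROI reason.  The chain is scale-covariant, so the
arbitrary fluorescence units cancel.

**Smoothing width.** The pre-median smoothing sigma defaults to 0.5 s.  The
median in a 60 s window rejects transients only while the *smoothed*
responses occupy less than half the window; at task press rates (one press
per ~8 s, kernels visible for ~1.5 s) a 2 s sigma smears events past that
breakdown, and the baseline then tracks block-specific activity.  The
consequence is worth spelling out because it is a genuine property of
percentile baselining, not an implementation quirk: any context-dependent
response amplitude then leaks into a block-wide DC offset of ΔF/F, making
"context" linearly decodable at every time point of the trial.  0.5 s keeps
the smeared duty cycle below the breakdown while still suppressing frame
noise (15 frames FWHM ≈ 0.4 s).  The parameter is configurable.

## Peri-event analysis and clustering

Windows are −5..+5 s at 30 Hz, sample count = round(span·rate) + 1 with the
centre sample exactly at the event frame (nearest *preceding* frame — the
causal alignment convention).  Quantification windows are half-open
[t0, t1), so 0–200 ms bins are bit-reproducible.  Trials with any |z| above
the artifact threshold (default 10) or truncated by session edges are
invalid and never enter averages.

Clustering follows the chain's normative description — Ward linkage on
Euclidean distances between cue-aligned cued-trial averages over −2..+2 s,
dendrogram cut at k = 3.  Canonical labels are assigned by phenotype:
label 2 is the cluster with the largest cue-aligned/press-aligned peak ratio
(earliest cue peak breaks ties); of the rest, label 1 is the cluster whose
press-aligned peak sits at the press, using cross-context peak similarity
only to break coarse latency ties.  Peak similarity alone cannot separate
action from post-action ensembles whenever context gains are sign-balanced
(both gaps are then noise-level and the comparison favours whichever cluster
is larger); peak latency is the robust phenotype marker (action ≈ kernel
peak after the press, post-action ≈ 1 s later).  Remaining ties fall back to
cluster size and are logged.

Group comparisons expose the field's standard battery: Student's/paired t,
Mann-Whitney, Wilcoxon signed-rank (zsplit zero handling, so identical
groups give p = 1), and one-way ANOVA with Tukey-Kramer post-hocs.

## Trajectories

The 3-PC basis is fit on the time-concatenation of the two condition
averages (ROI-wise centred, no standardisation — traces are already
z-scored); both averages are projected into the shared basis and the
divergence is the per-sample 3-D Euclidean distance.  The permutation null
permutes condition labels across valid trials and re-runs the *entire*
pipeline per shuffle (conservative; a fixed-basis mode exists), keeping
every permutation including the identity.  The grand-average control is the
absolute difference of the two population-mean traces: a planted effect that
is mean-zero across neurons moves the trajectory distance but not this
control — the dissociation between pattern and rate codes.

## Decoding

66 ms bins = 2-frame means over a −2..+2 s window (60 bins; an odd leftover
frame is dropped and logged).  Classes are balanced to the minority count by
seeded subsampling.  Per bin, an independent linear SVM (C = 1; results at
the planted effect sizes are insensitive to C) on trials × neurons features,
stratified 10-fold CV (folds reduced with a warning if a class is smaller);
weights per bin come from a fit on all balanced trials.  The null permutes
labels once per repeat — the same permutation across bins, preserving
temporal structure — and re-runs the full CV; 100 repeats by default.
SVM1b restricts cued trials to a reaction-time bin (default 334–666 ms so
the −495..−165 ms evaluation window precedes movement on every trial) and
reports the mean accuracy over the evaluation bins alongside the full
curve.  SVM2 samples baseline epochs from ITI moments at least 2 s from any
press, cue or reward, count-matched and binned identically.  Axis
comparisons use unit-normalised weight vectors at each decoder's
peak-accuracy bin (cosine, plus Spearman correlation of absolute weights);
projections use the unit axis per trial and bin.

## Calibration scenarios

The validation suite runs on scenario sessions (`leverpop.scenarios`) whose
design needs justification, because a naive "no-effect" session is *not*
effect-free:

* cue transients precede cued presses — a real pre-press context signal;
* self-paced inter-press gaps (ITI 2–3 s) are short enough that the previous
  trial's reward response intrudes into the pre-press window on a fraction
  of self-paced trials only;
* unequal event densities between block types shift the windowed-median
  baseline per block (see above).

A permutation test or decoder *should* detect all of these.  Null
calibration therefore uses an action-only population with matched
press-to-press gap distributions across contexts (self ITI widened to
5.5–10.5 s with a short self reaction time, mirroring cued ITI + hold + RT)
and no unrewarded presses, making labels exchangeable by construction.  The
divergence, axis-dissociation and ablation scenarios build on the same
timing-matched base so that the only context information is the planted
one.  The clustering-recovery scenario keeps amplitude heterogeneity small
(±10%) so archetype shape is the only planted cluster structure; with broad
amplitude spread a Euclidean k = 3 cut can legitimately split the largest
ensemble by amplitude instead.

## Problem sizes and numerical choices

Validation runs use sessions of 1–3 block pairs with 12–25 rewards per
block, 30–300 neurons, 100-shuffle trajectory nulls (20 replicates for
coverage), 15–30-repeat decoder nulls, and 50 replicates for decoder chance
calibration; the full suite and the reproduction script each run in minutes
on one CPU.  Tie-breaks and degenerate inputs: identity permutations are
kept in nulls; zero-variance lever segments and empty blocks report NaN
(missing), never 0; single-archetype populations forced to k = 3 still get a
bijective canonical labelling (logged).  Seeds: every stochastic routine
takes an explicit seed; identical seeds give bit-identical outputs.

## Known limitations

Percentile-baseline leakage (above) is inherent to the method and bounded,
not removed, by the 0.5 s smoothing choice.  Press-frame discretisation at
30 Hz adds jitter noise at the steep transient rise, visible as small
post-press fluctuations of divergence curves on single sessions.  The
SVM1b latency-matching assumes reaction times are measured exactly; with
real data, movement onset before the threshold crossing would blur the
"pre-movement" claim.  The decoders quantify linear separability only.
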