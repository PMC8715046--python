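# Methods

This note documents the analysis model, the synthetic-data generator, and
the numerical choices behind `pupilkit`, in the spirit of a package
methods appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

The measured signal is pupil *area* per eye at a fixed rate (250 Hz by
default).  Assuming a circular pupil, diameter is `d = sqrt(4*A/pi)`;
the conversion is exact and strictly monotone, so it commutes with the
ordering of all later statistics.  Smoothing is a centred moving average
over 20 ms (5 samples at 250 Hz), computed over non-missing samples only;
at the recording boundaries the window shrinks to the available samples.
Missing data are represented by a boolean mask throughout — never by
sentinel values, and never interpolated.

**Blink detection.**  A blink appears as a rapid collapse and recovery of
the measured area.  The detector computes the first difference of the
smoothed diameter and flags samples whose velocity exceeds
`blink_velocity_k` (default 5) robust standard deviations — median
absolute deviation × 1.4826 — of the velocity over the recording.  The
robust scale is insensitive to the blink transients themselves and adapts
to device units.  A run of rapid decreases opens a blink; the blink closes
at the end of the first rapid-increase run completing within the 500-ms
pairing window.  Unclosed decreases are masked for a full pairing window
as a precaution and reported with `paired=False`.  Each blink masks
`[onset − 40 ms, offset + 80 ms]`; overlapping padded masks are merged.
The velocity threshold is adaptive because an absolute threshold in
device units would not transfer across trackers; `k = 5` was chosen once
as a conventional robust-outlier cutoff.  Detection quality is measured
(not assumed) against the generator's ground-truth manifest in the test
suite.

## Epochs and condition means

Each trial yields an epoch over `[−1 s, duration + 1 s)` relative to cue
onset, on the acquisition grid, with the onset snapped to the nearest
sample (alignment error ≤ 2 ms at 250 Hz).  Baseline is the mean diameter
over the 100 ms immediately preceding the cue; the epoch is expressed as
change from baseline.  An epoch whose baseline window is entirely missing,
or which extends past the recording, is flagged unusable and excluded
from averages — no other trial-exclusion heuristic is applied (in
particular, no exclusion for heavy blink loss: the pointwise non-missing
mean handles partial loss).  All analysis windows are half-open
`[start, end)` in seconds.

Condition means are pointwise non-missing averages of usable epochs within
a participant × eye × drug (× duration) cell.  When durations are pooled,
the mean at time *t* uses every epoch whose span covers *t*, so the
per-timepoint trial count varies along the grid.  Group-level curves are
means of participant-level means, not trial-pooled means, so each
participant carries equal weight.

## Dilation-onset latency

The estimator operates on a baseline-corrected mean trace.  *P* is the
maximum of the trace within a search window after cue onset, default
`[0, 3]` s — the shortest trial length.  The window deliberately brackets
the *initial* peak of the response and excludes late sustained drift; a
global maximum over a 9-s trial would often sit on the sustained plateau
rather than the onset transient.  *t₂₅* and *t₇₅* are the first
below-to-above crossings of 0.25·P and 0.75·P before the peak, located by
linear interpolation between samples; the latency is the
zero-intersection of the chord through `(t₂₅, 0.25 P)` and
`(t₇₅, 0.75 P)`.  If both crossings lie on a linearly rising segment, the
estimate equals the segment's zero-crossing exactly, independent of the
precise peak value — the property that makes the method robust to modest
peak misestimation and to smoothing-induced peak attenuation.

A trace with *no apparent increase* is reported as `failed` rather than
given a meaningless number.  The implemented criterion — peak below
3 × the SD of the pre-cue segment, configurable — is an explicit,
testable stand-in for a judgment that is usually made by eye; it should
not be read as a published rule.  Estimation is per participant per eye
on the across-trial mean trace by default (per-trial traces are too noisy
for crossing detection); invariances (time-shift equivariance, amplitude
invariance) are exact by construction and regression-tested.

Movement latency is the time of the first button press within a trial,
relative to cue onset; trials without a press are flagged and excluded
from summaries.

## Statistical layer

**Repeated-measures ANOVA.**  For complete balanced within-subject data,
every effect (main effects and interactions) is tested against its own
participant-by-effect interaction, `df = (n−1)·Π(levels−1)`.  Sums of
squares are computed by inclusion–exclusion over marginal means; on
balanced data the decomposition is exact
(`SS_total = Σ effects + Σ errors + SS_subjects`, verified to 1e-8
relative on randomized tables).  Incomplete or duplicated cells raise an
error naming the cells; nothing is imputed.  No sphericity correction is
applied by default, matching the uncorrected degrees of freedom such
analyses conventionally report; Greenhouse–Geisser is available via
`rm_anova(..., gg=True)`.

**Pooled-error simple main effects.**  The simple effect of factor A at
fixed levels of factors F pools the error terms `subj × (A ∪ T)` for every
`T ⊆ F`.  In a 2×2×4 design with n = 14 and both other factors fixed this
gives a denominator of (n−1)·(1+1+3+3) = 104; with one factor of a 2×2×3
design fixed it gives (n−1)·(1+1) = 26.  This pooling convention is
common in the psychology literature that reports such df patterns; a
cell-wise error term is available via `pooled_error=False`.

**Ryan's procedure.**  Group means are ordered; the comparison spanning
*r* ordered means is judged at nominal level `α′(r) = 2α/(k·(r−1))`,
testing from the widest span inward; a pair is significant only if its
own p-value is below its nominal level *and* every enclosing span's
comparison was significant.  t statistics use a shared error mean square
(from the preceding ANOVA) with its degrees of freedom.  Several variants
of sequentially rejective range procedures exist; this implementation is
the level-adjusted variant stated above, documented here precisely
because the name "Ryan test" alone does not pin down the variant.

**One-way ANOVA** is the classical between/within decomposition,
df = (k−1, N−k).  A summary-statistics path reconstructs the identical F
from per-group (mean, SD, n), since `SS_within = Σ(nᵢ−1)sᵢ²` exactly;
raw-data and summary paths agree to 1e-10 in tests.  Zero within-group
variance yields F = 0 with a warning rather than an exception.

## Synthetic-data generator

The generator emulates the *design* of a two-eye mydriatic study:
14 participants, treated vs. control eye, sessions of 30 trials (10 each
of 3/6/9 s in random order), inter-trial interval uniform on 5–8 s,
250-Hz area samples per eye, button presses with truncated-normal
reaction times (mean 0.56 s, SD 0.09 s).

The evoked dilation is the sum of two components above a resting
baseline:

* **fast**: a linear ramp starting `fast_latency` (0.6 s) after cue onset
  and reaching `fast_amplitude` (0.6 mm) at the initial peak 0.88 s later
  (i.e. 1.48 s post-cue), then relaxing exponentially (τ = 0.8 s) toward a
  plateau fraction (0.6);
* **slow**: a saturating-exponential rise (τ = 1.5 s) starting at the fast
  peak, held until cue offset, amplitude 0.25 mm.

After cue offset both components decay with τ = 1 s.  The fast rise is
*linear* by design: the 25/75 chord of a linear ramp extrapolates to the
true onset exactly, which gives the latency tests a sharp ground truth
(a saturating-exponential rise would displace the chord intersection by a
fixed fraction of its time constant and make "exact recovery" undefined).
The component shapes are phenomenological stand-ins that reproduce the
qualitative response pattern — rapid rise to an initial peak, sustained
elevation, post-offset return — not a biophysical iris model.

Drug presets modify the treated eye only: *tropicamide-like* halves the
fast amplitude, delays the fast onset by 0.35 s, scales the slow component
by 0.6 and raises the resting baseline to ≈ 7 mm; *phenylephrine-like*
removes the slow component and raises the baseline to ≈ 6.4 mm; *control*
leaves the eyes statistically identical.  Between-participant variability:
amplitudes share a log-normal multiplier (CV 0.2), the fast latency is
normal (SD 0.08 s), resting baseline normal (SD 0.5 mm); component
parameters are shared between the two eyes of a participant, so
treated-minus-control contrasts isolate the preset effect.

Nuisance processes: hippus as a 0.2-Hz sinusoid (amplitude 0.05 mm,
random phase and ±10% frequency jitter per recording); blinks as a
Poisson process (0.15 events/s, duration uniform 0.10–0.25 s) implemented
as multiplicative area collapses to 2% with 8-ms edges — guaranteeing the
rapid-decrease/increase signature; additive Gaussian sensor noise on area
(SD 0.3 mm², ≈ 0.04 mm of diameter noise at 4.7 mm).  The trace is emitted
as *area* via the inverse conversion so the pipeline's own conversion is
exercised.  Every drawn value (component parameters, blink intervals,
reaction times) is recorded in a ground-truth manifest; recovery tests
key off the manifest, never off re-simulation.  The default parameter
table is shipped as a versioned fixture file
(`src/pupilkit/data/default_params.cfg`) and pinned to the dataclass
defaults by a unit test.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: pharmacokinetic drug onset over tens of
minutes, the pupillary light reflex and luminance coupling, gaze-dependent
pupil foreshortening, partial-occlusion or saccade artifacts, tracker
dropout, non-stationary hippus, and any nonlinear interaction between the
two muscle systems.  Results on simulated cohorts demonstrate the
pipeline's correctness and sensitivity under its own generative
assumptions, not the physiology.

## Problem sizes and tolerances

The test suite and acceptance script use desk-scale problem sizes chosen
once: single-session cohorts of 14 participants (30 trials per eye) for
end-to-end recovery, 100 replicates for the latency-noise and
significance-rate checks, 100 short recordings for blink-detection
quality, and 1,000 random tables for the sums-of-squares conservation
check.  Key tolerances: conversion exact to 1e-12; epoch baseline zero to
1e-9; latency exact to one sample (4 ms) on noiseless traces, median
absolute error ≤ 50 ms at 10%-of-peak additive noise; ANOVA decomposition
to 1e-8 relative; treated-eye latency shift recovered within ±0.10 s of
the injected 0.35 s.

## Known limitations

* The rm-ANOVA engine requires complete balanced data; unbalanced designs
  need a mixed-model approach that is out of scope.
* Blink detection assumes full-occlusion collapses; graded partial
  occlusions may evade the velocity threshold.
* The latency estimator fails (by design) on traces that start above 25%
  of their peak or never rise above the baseline-noise criterion; such
  participants are reported as `failed`, mirroring the practice of
  excluding "no apparent increase" cases, but with an explicit rule.
* The native area unit of a given tracker is not guessed;
  `area_unit_scale` must be set by the user if the export is not mm².
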