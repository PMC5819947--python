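# Methods

This package re-implements, as a tested pipeline over synthetic data, an
analysis of movement-related gamma (40–90 Hz) activity in subthalamic
local field potentials (LFP): kinematic event detection, Morlet
time-frequency maps of event-related synchronisation/desynchronisation
(ERS/ERD), percentile-thresholded gamma-burst detection with
burst-property statistics, single-trial power–velocity correlation
maps, and Monte-Carlo permutation statistics with FDR and cluster-size
control. Patient LFP recordings of this kind are not public, so a
seeded synthetic session generator stands in for the recordings; it is
first-class, tested code, and everything it injects is recorded as
ground truth so that the analysis stages can be scored against it.

## The synthetic session

One session emulates one hand of one subject performing cued forearm
pronations of three amplitudes (30°, 60°, 90°; 15 trials each,
randomised order, 4 s inter-trial periods), with LFP from two
electrodes ("contra" and "ipsi" to the moved hand), three bipolar
contact pairs each, all sampled at 1 kHz.

**Movement.** Each trial draws a reaction time (normal, mean 0.65 s,
SD 0.10 s, floor 0.2 s) and a minimum-jerk rotation to the target
angle over a per-condition base duration (0.45/0.52/0.58 s) divided by
a lognormal per-trial speed factor (σ = 0.12); the handle is held 3 s
and returned. Minimum jerk is the simplest profile with the
single-peaked ("bell-shaped") velocity that the peak-velocity landmark
assumes; its peak velocity is 15/8·A/T, which makes the true per-trial
peak velocity available in closed form. Potentiometer noise is white
(SD 0.15°).

**LFP.** Per channel, independently: 1/f^α background (α = 2.0, unit
broadband SD — the arbitrary µV-like scale is inert because all
detection thresholds are data-relative percentiles), a 50 Hz line
component (amplitude 0.25), a tonic 20 Hz beta oscillation (amplitude
0.45) whose amplitude drops by 25% in a smoothed window −0.4…+1.7 s
around movement onset (ERD), a 5 Hz theta oscillation gated ON in
−1.2…+2.7 s (ERS), and gamma bursts: Hann-windowed 70 Hz sinusoids,
1–3 cycles long (mean 1.9), amplitudes lognormal around 1.2, occurring
as an inhomogeneous Poisson process (thinning, with a refractory gap of
one burst duration so bursts never overlap). The Poisson intensity is
3.2 bursts/s at rest (1.6 per 0.5 s) and rises during the 0.5 s after
movement onset by a per-condition gain (29.3/36.7/48.2% for
small/medium/large). On the contra electrode only, the per-trial gain
is additionally multiplied by (1 + κ·z), where z is the standardised
log speed factor and κ = 1.2 — rate, not amplitude or duration, carries
the movement and velocity information. In the simulated "OFF
medication" state only this movement-related rate gain is scaled down
(default ×0.5); amplitude and duration distributions are untouched, so
medication-state comparisons of those properties have an exactly true
null.

### What the generator emulates, and what it does not

It reproduces the signal structure the analysis assumes — band-limited
event-related power changes, rate-coded gamma bursting, velocity
coupling, a laterality difference, a medication effect confined to
burst rate. It does not attempt biophysics: no tremor or movement
artifacts, no electrode drift, no cross-frequency coupling, no volume
conduction (channels are independent, which real bipolar neighbours are
not), and the beta/theta components are single tones rather than
band-limited rhythms. Passing recovery tests therefore shows the
*pipeline* is correct and sensitive under the assumed structure; it
does not certify performance on real recordings.

### Calibration of the burst parameters

The study this emulates reports a baseline→movement window rate of
2.8→3.4 bursts per 0.5 s, but also 42.6 bursts per 5 s trial
(≈4.3/0.5 s) — mutually inconsistent numbers computed over different
windows. More importantly, the detector itself constrains what is
recoverable: thresholding a 100 ms-smoothed envelope at the 75th
percentile is a *threshold-crossing* statistic. When bursting is dense
enough that detected rates approach 2.8/0.5 s, envelope excursions
merge and the detected rate saturates (the smoothed bump of a 27 ms
burst is ~100 ms wide, capping countable excursions near 5/s), which
erases the injected condition ordering. The defaults were therefore
calibrated for recoverability of the condition and state effects —
injected baseline rate 1.6/0.5 s, detected baseline ≈1.1/0.5 s — and
the absolute window rates of the original study are treated as
order-of-magnitude anchors, not reproduction targets. The same
crossing-statistics argument explains why detected burst durations on
synthetic data (~100 ms at the default operating point) exceed the
original 27 ms: the smoothed bump of a single short burst is itself
~100 ms wide, and short crossings arise only when the threshold cuts
near the tops of a dense excursion process — the regime in which rate
recovery fails.

κ = 1.2 was set so that a 20-subject synthetic cohort shows a robust,
FDR-surviving gamma velocity-correlation cluster, emulating the
original study's robustly significant correlation map; at weaker
coupling the genuine effect is statistically invisible at cohort scale
and any apparent specificity test would in fact be exercising artifacts
(next section).

## Kinematics

Landmarks per trial: maximal amplitude (maxA) is the first maximum of
the movement trace in the trial window; maximal velocity (maxV) the
first maximum of its derivative (central differences, one-sided at the
edges); movement onset (MO) the last upward crossing of 10% of the
trial's peak velocity before maxV. Reaction time is MO minus cue;
accuracy is the percent deviation of maxA from the target angle.
The original procedure checked landmarks visually; this pipeline
substitutes a deterministic rule — a 5 Hz zero-phase low-pass on the
trace before differentiation — and flags trials instead (peak velocity
must exceed 5 deg/s; the landmark ordering cue ≤ MO ≤ maxV ≤ maxA must
hold).

A consequence worth knowing: for a minimum-jerk rise the 10% crossing
sits ≈0.079·T after the true movement start, so the detected onset
carries a small systematic, *velocity-dependent* delay (T shrinks as
velocity grows). In averaged analyses this is negligible; in
single-trial correlation maps it leaks velocity information into every
landmark-locked signal edge (see the correlation section).

## Preprocessing

Bipolar montage (adjacent contact pairs 01/12/23; pass-through when the
input is already bipolar). Fifth-order Butterworth high-pass at 1 Hz
plus fifth-order band-stop 48–52 Hz, both applied forward–backward:
zero-phase filtering preserves ERS/ERD timing and burst onsets at the
cost of doubling the effective order. Epochs span the closed interval
−2…+3 s around the alignment event (5001 samples at 1 kHz). Artifact
flags (never deletions): any sample beyond 6× the per-channel
MAD-based SD ("amplitude"), ≥10 consecutive identical samples
("saturation"), or an invalid behavioural trial. Thresholds are
data-relative and configurable; the qualitative criteria they encode
("artifacts and saturation") have no published numeric values.

## Spectral analysis

Morlet wavelets, 7 cycles, integer frequencies 1–100 Hz, FFT-based
convolution batched over trials and channels; samples within one
temporal SD of an epoch edge are flagged invalid rather than silently
zero-padded (at 1 Hz the wavelet outlives the epoch — those rows are
edge-flagged everywhere rather than rejected). Power is baselined to
percent change per frequency and channel. The stated baseline window
"−2 to 0.5 s preceding the cue" is internally ambiguous; it is read as
−2.0…−0.5 s *before* the cue (the only reading in which the whole
window precedes the cue), and since epochs here are aligned to movement
onset, the pipeline uses −2.0…−1.0 s relative to onset, which lies
before the cue for typical reaction times. The baseline statistic is
the across-trial arithmetic mean of the within-window mean; a bisquare
robust variant and a per-trial variant are options. (The arithmetic
default is what makes "baseline-window mean exactly zero" an exact
invariant; with the robust statistic it holds only approximately.)

Smoothing is a separable Gaussian, FWHM 6 Hz × 200 ms (the SPM reading
of "smoothed over"), unit-mass kernel with renormalised truncation at
the edges. Trial averaging is a bisquare iteratively-reweighted robust
mean (MAD scale, c = 4.685, ≤20 iterations; residual-SD fallback when
the MAD degenerates). Band summaries average the percent-change map
over theta 2–8, beta 13–30 or gamma 40–90 Hz in the 0–0.5 s movement
window, then hierarchically: contact pairs → electrode/hemisphere →
subject (the order matters with unequal group sizes and is asserted by
a test).

## Burst analysis

Envelope: fifth-order Butterworth band-pass 40–90 Hz (zero-phase) on
the line-filtered continuous recording, rectification, then smoothing
with a Gaussian kernel of 100 ms total length (SD = length/6; the
source description "moving average gaussian kernel" is contradictory —
a boxcar alternative is a config option). The 50 Hz line is removed
first because it sits inside the band and would otherwise inflate every
envelope.

Threshold: 75th percentile (linear-interpolation order statistics) of
the pooled envelope samples of all contact pairs of one electrode over
the entire continuous recording — pooled per electrode rather than per
pair, matching the "same threshold for all contact pairs of one
electrode" description. A burst is a maximal run of strictly
supra-threshold samples lasting at least one gamma cycle at the
subject-level gamma peak frequency; its amplitude is the area between
envelope and threshold. The subject gamma peak is the maximum, within
40–90 Hz, of the movement-window spectrum expressed relative to its
fitted 1/f background (log–log fit on 24–38 ∪ 110–240 Hz;
background-*subtracted*, because dividing by a falling background drags
the maximum of a broad bump upward in frequency, and because
normalising by the pre-movement baseline spectrum divides the bump out
entirely — baseline bursting differs from movement bursting only in
rate). Monotone profile → no-peak flag and 65 Hz fallback; ties take
the lower frequency.

Burst rate is counted per 0.5 s window — movement 0…+0.5 s after
detected onset, baseline −2…−1.5 s — with window membership decided by
burst onset (no double counting). Condition-wise rates are compared
against the session-wide pooled baseline: pre-cue activity carries no
condition effect, and a shared baseline cancels from condition
contrasts, which measurably improves their precision. For
medication-state comparisons the OFF recording is thresholded with the
matched ON electrode threshold.

A quantitative consequence, measured directly: a configured +40%
movement rate gain over 200 single-condition trials is detected as a
+19 ± 2% rate change (8 sessions). The attenuation to roughly half has
three sources — the whole-recording percentile threshold adapts upward
with overall rate, envelope excursions merge (the smoothed bump of one
burst is ~100 ms wide), and a share of detected crossings are
background excursions that carry no modulation. At the extreme
sparse/high-amplitude end a fourth mechanism takes over: the band-pass
filter's ringing around a large burst crosses a comparatively tiny
threshold for hundreds of milliseconds and detection degenerates. The
detector is therefore treated throughout as a *biased but monotone*
estimator of rate modulation: orderings and contrasts are recoverable,
absolute percent changes are not.

## Statistics

Monte-Carlo permutation tests (default 5000 draws): paired sign-flip of
within-unit differences, two-sample label exchange, or one-sample
sign-flip, with the two-sided conservative estimator
p = (r+1)/(n+1). Benjamini–Hochberg FDR at α = 0.05 (statsmodels'
step-up behind the module surface; an exhaustive brute-force oracle
checks it in the tests). Significance masks on time-frequency grids
are filtered to 4-connected clusters of ≥150 bins, FDR first and
cluster filter second. Correlation between per-subject summaries and
clinical scores is Pearson when both variables pass a
Lilliefors-corrected Kolmogorov–Smirnov normality check, Spearman
otherwise. The velocity-correlation map computes within-subject
Spearman ρ between single-trial power and trial peak velocity in every
bin, then a one-sample sign-flip permutation test on the per-subject ρ
per bin, then FDR and cluster filtering.

A practical resolution limit worth stating: with n_perm permutations
the smallest achievable p is 1/(n_perm+1), and BH over m bins can only
reject at all if roughly m·p_min/α bins reach that floor. At 5000
permutations and a 100×501 map this means ≥~200 floor-level bins are
needed before anything survives; the cohort-level correlation analysis
therefore uses 20 000 permutations.

## Single-trial correlation maps: two structural findings

Piloting the specificity analysis (coupling injected only as gamma
burst rate on contra channels) surfaced two effects that shape the
tests:

1. **Landmark-locked timing leak.** Because the detected onset is late
   by ≈0.079·T and T co-varies with velocity, aligning single-trial
   maps on detected landmarks shifts every signal edge (theta ERS,
   beta ERD) by a velocity-correlated amount. Across enough trials and
   subjects this produces genuine, systematic low-frequency
   "correlations" on both hemispheres that have nothing to do with
   injected coupling. The specificity test therefore aligns maps on
   ground-truth onsets (exactly what the generator's GroundTruth is
   for); on real data, where no ground truth exists, this bias is an
   inherent caveat of landmark-locked single-trial correlation maps.

2. **Spectral width of short bursts.** A 1.9-cycle 70 Hz burst seen
   through a 7-cycle wavelet responds from ~33 to beyond 100 Hz (still
   74–95% of peak at 90–100 Hz). Velocity-coupled bins therefore
   *cannot* be confined to the nominal 40–90 Hz band; the honest
   specificity statement is confinement to the numerically measured
   spectral support of the injected waveform, with the bulk inside
   40–90 Hz and nothing in the theta/beta rows.

## Problem sizes

Test and acceptance runs use desk-scale problem sizes, chosen as the
package's own defaults: parameter-recovery uses simulated cohorts
(cohort sizes stated in the tests; the condition-ordering and
medication-state contrasts are cohort-level claims — per-subject
Poisson counting noise at 15 trials/condition caps the per-subject
standardised effect near z ≈ 0.5, so no single-subject analysis can
recover ordering reliably), the correlation map uses 20 simulated
subjects, and null calibrations use hundreds of Monte-Carlo
repetitions. The acceptance script reports cohort means over 8
subjects for burst statistics and 3 subjects for time-frequency
summaries; at those sizes the reported condition-wise rate changes are
still individually noisy (±4 points), which is visible in the output
and intended. A related resolution note: the group sign-flip test's
smallest achievable p is 2/2^n over n subjects, so bin-wise FDR on full
maps needs cohorts of roughly 16 subjects or more regardless of the
permutation count.

## Known limitations

* Detected burst rates and durations live in the crossing-statistics
  regime discussed above; absolute values are not comparable to the
  original study's printed rates, only the relative contrasts are.
* The generator's channels are statistically independent; real bipolar
  derivations share contacts and volume-conducted sources.
* ERS/ERD onset/offset latencies depend on the wavelet cycle number and
  are reported but nowhere asserted.
* The clinical table is a transcription; its printed cohort means for
  age (59.5) and disease duration (11.8) do not match recomputation
  from the printed rows (58.9, 11.2) — the package reports the
  recomputed values and leaves the discrepancy visible.
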