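# Methods

## Scope and model

The package analyzes three-channel LFP (OB, EC, dHPC; 1 kHz sampling,
signal band below 250 Hz) recorded while a rodent performs the test
phase of a novel object recognition task in a 75 × 75 cm arena, with
synchronized body/nose tracking. The analysis chain is:

1. preprocessing (baseline, mains notch, low-pass, artifact masking);
2. behavioral scoring (exploration bouts, discrimination index,
   locomotion);
3. event-locked epoching around novel-object bout onsets
   (2 s pre, 1 s post);
4. per-pair connectivity: Welch magnitude-squared coherence and
   normalized cross-correlation with lead–lag readout;
5. positional coherence maps (descriptive);
6. cohort statistics.

A synthetic-cohort generator provides known-truth data for every
stage; all acceptance testing is parameter recovery against it.

## Synthetic data: what it emulates, and what it does not

Per band b (theta 4–12 Hz, gamma 30–80 Hz by default) one shared
source s_b — white noise band-passed with a zero-phase Butterworth
filter and rescaled to variance σ²_b — is mixed into region r as
g_{r,b}·s_b(t − d_{r,b}) plus independent 1/f-shaped background noise
(power ∝ 1/f, floored below 1 Hz so DC power is finite, rescaled to
the target variance; exponent 0 gives white noise). Delays are integer
sample shifts, so injected lead–lags are exact by construction;
defaults are 0/20/35 ms for OB/EC/dHPC, i.e. OB→EC 20 ms and
EC→dHPC 15 ms, identical in both bands so the broadband mixture has a
single well-defined delay. The impaired ("Aβ-like") group scales all
gains by `group_gain_factor` (default 0.5).

The analytic per-frequency coherence of a pair is
MSC(f) = SNR_x SNR_y / ((1+SNR_x)(1+SNR_y)), with SNR_r(f) the ratio
of the region's mixed-source PSD (|H(f)|⁴-shaped, since filtering is
forward–backward) to its noise PSD; both densities are normalized to
the realized variances. Band-level ground truth is this curve averaged
on the analysis frequency grid (1 Hz bins, matching 1 s Welch
segments): the in-band MSC falls steeply at the band edges, and
averaging theory and estimate on different grids would bias the
comparison by up to ~0.05 in theta without any estimator error.

Tracking is a clipped Ornstein–Uhlenbeck walk confined to the central
third of the arena, with inserted dwell bouts at two objects placed
15 cm from opposite corners (radius 5 cm, matching 10 cm-diameter
objects). During a bout the nose sits within 2.5 cm of the object
center (0 cm from its surface); outside bouts the walk keeps the nose
beyond the threshold of both objects. Dwell is split
p_novel : (1 − p_novel) on the 25 Hz tracking grid, so DI_true =
2·p_novel − 1 is recovered up to one-sample discretization. Per
animal, p_novel and the dwell budget are jittered
(SD 0.05 and 20 % respectively) to give cohorts realistic
between-animal spread.

Default group conditions mirror the emulated study: 6 animals per
group, 4-minute sessions; control p_novel = 0.7876 with 5.65 s total
dwell, impaired p_novel = 0.5494 with 3.60 s (back-derived from the
reported percent and absolute exploration times). Note the generator's
DI is tied to p_novel by the identity above, so group-mean DI (~0.58
vs ~0.10) follows the percentage conditions rather than matching any
separately reported DI summary.

Deliberately not modeled: biophysical network dynamics, respiration
locking, spike activity, nonstationary coupling, tracking noise or
kinematically smooth approach paths, and electrode artifacts beyond
amplitude outliers. Passing recovery tests therefore demonstrates
estimator correctness under the stated statistical structure, not
robustness to every failure mode of real recordings.

## Preprocessing choices

"Baseline correction" is per-channel mean subtraction. The mains
notch (50 Hz default, 2 Hz stop-band; 60 Hz configurable) and the
250 Hz low-pass are hard rFFT masks: exactly zero-phase (protecting
lag estimates), and exactly idempotent — re-preprocessing clean data
reproduces it to numerical precision, which no IIR realization with
non-{0,1} gain achieves. A pure 50 Hz tone is attenuated far beyond
the 20 dB requirement. Artifact handling marks samples whose absolute
z-score exceeds 6 on any channel, dilated ±100 ms, in a boolean mask;
masked data are never interpolated, and epochs or map windows touching
the mask are dropped whole. Band-passing for cross-correlation uses a
zero-phase (forward–backward) 4th-order Butterworth; the squared
response gives a maximally flat passband and ≥ 40 dB one octave out.

## Behavior

The 2.5 cm exploration criterion is measured nose-to-object-surface
(center distance minus radius, floored at zero): with 10 cm-diameter
objects a center criterion is unsatisfiable, but a `to_surface=False`
flag provides the center reading for narrow objects. Bouts are maximal
sub-threshold runs, bounded by the first and last sub-threshold
samples; no minimum duration by default (configurable). Zero total
exploration yields DI = NaN (missing), never 0. Traveled distance
median-filters the body trace over 5 samples before step-summing to
avoid jitter inflation. Bouts starting earlier than the 2 s pre-window
are kept by the scorer and dropped at epoching.

## Connectivity

Epochs are 3 s (2 s pre / 1 s post onset) and must be fully inside the
recording and mask-free. Coherence uses 1 s Hann segments with 50 %
overlap (5 segments per epoch, 1 Hz resolution); by default segments
are pooled across an animal's epochs into one estimate (stable for few
trials), with a per-trial averaging switch. At least two segments are
required — a single segment makes MSC identically 1. The estimator's
small-sample bias for independent signals is ≈ 1/K segments and is
verified by simulation.

Cross-correlation is computed per trial on band-passed, mean-removed
epochs with the "coeff" normalization, and per-trial peak coefficients
and lags are averaged per animal. Sign convention, printed in every
output: positive lag = first-named region leads. The peak is the
signed maximum (an absolute-peak flag exists); ties break toward the
smallest |lag|, then the positive lag. Maximum lag defaults to 250 ms
for low bands (a theta-band correlogram repeats every ~125 ms, so the
grid must exceed one cycle) and 100 ms otherwise; lag-recovery
guarantees hold for delays under a quarter of the slowest band's
period. The "lag of information influx" is read out as this peak lag.

## Spatial maps

Non-overlapping 1 s windows are assigned to 5 cm spatial bins by the
window's mean body position (assignment rule and sizes are declared
assumptions); each bin's value is the band-averaged pooled coherence
of its windows (one Welch segment per window), reported only at
occupancy ≥ 3 (configurable; below 2 the estimate is degenerate).
Occupancies sum to the number of unmasked, tracked windows. Maps are
visualization outputs; no statistics are derived from them.

## Statistics

Normality screening is Lilliefors-corrected KS (naive KS behind a
flag); failures warn and proceed, mirroring the source design in which
all data passed. Group contrasts use Student's equal-variance t
(Welch behind a flag; the original analysis does not specify).
One-sample t against 0 (or 100) handles zero-variance samples by
convention: p = 1 if the constant equals the null value, else p = 0
flagged degenerate; the same convention applies to two constant
groups. Pearson correlations are screened once for a single outlier:
Grubbs (closed-form critical value) on the externally studentized
residuals of the y-on-x regression at α = 0.05, at most one removal,
both fits reported with the removed animal id. "Significant outlier"
is concretized this way because the source names no procedure; both
variables are screened jointly through the residuals. No
multiple-testing correction by default (matching the emulated
analysis); Holm adjustment is available. α = 0.05 throughout.

## Problem sizes and determinism

Recovery tests use 300 s single sessions (coherence within ±0.05 of
theory; lags within ±1 sample). Power and false-positive properties
use 50 replicate cohorts of 6 + 6 animals at 120 s per session — sizes
chosen to give stable Monte-Carlo estimates at desk scale; at the
designed effect (half gains) per-cohort contrasts are essentially
always detected, and null cohorts show per-test false-positive counts
consistent with Binomial(50, 0.05). All randomness flows from
numpy SeedSequence spawning: one seed reproduces every file
byte-identically. Report files contain no timestamps; logs (which do)
are written separately.

## Known limitations

- EDF files can be read (via mne, optional extra) but not written;
  delimited text is canonical on disk.
- The 1/f background model and its exponent are assumptions, recorded
  in the manifest; real noise floors differ.
- Theta-band lag estimates from short epochs can jump by one cycle in
  low-SNR trials; per-animal averaging mitigates but does not remove
  this.
- The pooled-segment coherence couples an animal's trials; per-trial
  mode exists but is noisier for 5-segment epochs.
- Spatial maps inherit occupancy bias: sparsely visited bins are
  reported missing rather than estimated.
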