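# Methods

`miniscape` re-implements, as a tested library plus narrative analysis
scripts, the downstream analysis of single-photon microendoscopic Ca²⁺
imaging recorded during self-initiated movements and an auditory operant
conditioning task, together with a synthetic-session generator that
reproduces the statistical structure the analysis assumes.  This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic tests do and do not establish.

## Kinematics

Total body acceleration (BA) is the per-sample Euclidean norm of the three
head-accelerometer axes (anteroposterior, mediolateral, dorsoventral), in
units of g.  In a behaving mouse the BA distribution is bimodal — a rest
mode and a movement mode — and the movement threshold is the midpoint
between the two histogram peaks.  The original analysis set this threshold
by eye; `find_movement_threshold` automates the stated rule: 100 histogram
bins over the observed range, a 5-bin moving-average smoothing, peaks = the
two highest local maxima at least 5 bins apart, plus a valley criterion
(the trough between the candidate peaks must fall below half the lower
peak) so that unimodal data raise a distinct error instead of latching onto
a shoulder maximum.  Frames with BA above threshold are movement frames;
maximal runs of movement frames are bouts (minimum length one frame —
no minimum is stated for the original analysis).  Accelerometer traces
sampled faster than the imaging clock are block-averaged to 15 frames/s
before thresholding, since every downstream window is defined in imaging
frames.

Acceleration-change amplitude of an onset = max BA in the 2 s after the
onset minus BA at the onset; amplitudes are split into within-session
quartiles (Q1 "small" to Q4 "large"), boundary ties going to the lower
quartile for determinism.  The same classification applies to cue onsets.

## Trace processing

ΔF/F = (F − F₀)/F₀ with F₀ the minimum over the means of 2 s windows
placed at 1 s steps across the whole recording (a final window anchored at
the trace end covers any remainder).  Ca²⁺ events are local maxima of the
ΔF/F trace whose height exceeds both 2 SD of the full-session trace and the
magnitude of the largest negative deflection; plateau peaks take their
first frame.  The SD is deliberately computed on the full session (the
source analysis states no window).

Annulus ROIs sample the local neuropil: a ring with the same pixel area as
its somatic ROI, whose inner radius is the distance from the ROI's center
of mass to its farthest pixel plus five pixels.  Rasterization: the ring is
the |ROI| pixels nearest the center among pixels at distance ≥ inner
radius (ties broken by distance, then row-major index), which matches the
area exactly and implies an outer radius of √(inner² + area/π) up to
discretization.

For the soma/annulus kinetics comparison only, the annulus raw trace is
subtracted from the soma raw trace before ΔF/F; both signals are averaged
around detected somatic peaks and each average is fitted with
a·exp(−t/τ) + b from the peak over a 3 s window (`curve_fit`, τ bounded in
[10⁻⁴, 60] s; a flat segment or non-convergence raises a distinct error).
For annulus averages the fit can be anchored at a supplied peak index,
because the global maximum of a slow background average need not coincide
with the somatic event.

## Response significance: circular-shift bootstrap

For each neuron and event type, the event-triggered average (ETA) is the
mean ΔF/F in a ±2.5 s (or ±5 s) window around event onsets; events whose
window crosses the session edge are dropped and counted.  The test
statistic is the area between the ETA and its own 85th-percentile line
over the single longest run of consecutive supra-threshold frames.  The
null distribution circularly shifts the full-session trace by a uniform
random number of frames (≥ 1) and recomputes the same statistic around the
same event times, 2,000 (or 5,000) times; p = (1 + #{null ≥ observed}) /
(1 + n_null) (add-one estimator, so p > 0 always), significant iff
p < 0.05.

Implementation: the ETA of a circularly shifted trace equals a window of
the circular event-triggered profile c[k] = meanₑ trace[(e+k) mod T],
computed once per neuron by FFT cross-correlation; all 2,000 null ETAs are
then windows of c.  This identity is exact whenever no retained event
window crosses the session edge (guaranteed by the edge-dropping rule) and
is asserted against an explicit roll-and-average oracle in the tests.  It
makes the 200-neuron calibration experiment run in under a minute.

The statistic is one-sided (supra-threshold area).  A two-sided variant
that also scores area below the 15th percentile is available
(`two_sided=True`) but off by default, matching the source procedure.
Significant neurons are labeled positively or negatively modulated by
comparing the mean ETA in (0, +1 s] against [−1 s, 0); exact ties label
positive with a warning.

Derived per-neuron and per-event measures: response reliability = fraction
of events followed by ≥ 1 detected transient within 1 s (defined for
positively modulated neurons); per-event population recruitment = fraction
of neurons with a transient within 1.5 s (22 frames, flooring) of each
event.  Cross-session overlap of responsive populations is compared with
the independence expectation p₁·p₂ (and, for k sessions, the
Poisson-binomial profile of "significant in exactly j of k sessions").
Cross-session cell registration rows are accepted iff p_same > 0.5 and
centroid distance < 14 µm (both strict).  Outliers use Tukey fences at
1.5 IQR.

## Pairwise correlations and distance

Rest windows: for every rest ≥ 2.5 s, one 2 s window starting 250 ms after
the preceding movement offset.  Movement windows: 2 s centered on each
onset.  Cue windows: 2 s from cue onset (the source does not state the cue
window; this default is configurable).  Pearson correlations are computed
per window and averaged across windows, one value per pair; windows in
which a trace is constant are skipped and counted, and pairs with no valid
window are omitted with a log entry.

Pairs are grouped into 10 µm centroid-distance bins (half-open, empty bins
dropped), each bin reduced to one unweighted mean, and the bin means
regressed on bin-center distance.  The slope estimate is plain OLS on the
bin means — the procedure being reproduced.  The slope p-value, however,
uses HC3 heteroskedasticity-robust standard errors: bin pair-counts span
more than an order of magnitude, sparse far-distance bins carry high
leverage, and in null simulations plain OLS rejected a true zero slope
~21% of the time at α = 0.05, versus ~5.5% with HC3.  `RegressionFit`
reports both R² and adjusted R² (the adjusted value can be negative for
null fits, matching the convention in which such values are reported).

## Joint PSTH with shift predictor

Each event repetition is a trial; detected Ca²⁺ events are binarized into
67 ms (one-frame) bins — at this width a bin holds at most one detected
peak, so indicators and counts coincide.  The raw JPSTH entry (t₁, t₂)
counts trials in which neuron 1 fired in bin t₁ and neuron 2 in bin t₂.
The shift predictor is the average of the raw JPSTH over all N−1 circular
trial shifts of neuron 2; the implementation uses the exact closed form
(outer(s₁, s₂) − raw)/(N−1), asserted equal to the explicit shift loop.
Corrected JPSTH = raw − predictor, smoothed with a 2-D Gaussian of SD 1
bin (truncated at 3 SD, edge-renormalized so borders are averages of
available bins rather than shrunk toward zero).

Normalization (default, `binwise`): each bin of raw − predictor is divided
by N·σ₁(t₁)·σ₂(t₂), where σ are the per-bin across-trial SDs of the
indicators — the classical JPSTH normalization, which turns every bin into
a trial-by-trial correlation coefficient.  Its decisive property is a
rate-independent noise scale: without it, bins at event-elevated rates are
intrinsically noisier than quiet-period bins, and the far-removed baseline
band comparison below is ill-posed (in simulations with independent
modulated pairs, the scalar-normalized diagonal peak exceeded the baseline
band in more than half of sessions for purely Poisson reasons).  The
scalar variant — dividing the smoothed corrected matrix by the product of
the SDs of the two PSTH curves — is available as `normalization='psth_sd'`
and as the standalone `normalize_jpsth`.  Bins without across-trial
variance are set to 0.  The population JPSTH is the elementwise mean of
the normalized matrices over pairs (optionally restricted to, e.g.,
positively modulated pairs); its diagonal is the time course of zero-lag
noise correlation.

Baseline band: the population JPSTH is recomputed around sham events — the
real event times circularly displaced by a random shift of at least 20 s —
over a 10 s diagonal window, and the mean ± SD of that diagonal define the
band.  The baseline-window peak (max over the 0.5 s before onset) and the
post-event peak (max over the 1.5 s after onset) are extracted per
session; across sessions these peak pairs feed a standard signed-rank
comparison.  Because a peak is a max statistic, a single session's peak
exceeds a ±2 SD per-bin band with ~15–30% probability even under the null;
peak-versus-band conclusions are therefore drawn from several independent
sessions (mirroring the per-animal design of the original comparison), and
the tests do the same.

## Synthetic sessions

The generator produces sessions under the stated study conditions:
15 frames/s, 30–60 min, 600 × 900 µm field at 1.2 µm/pixel, 42-trial
conditioning sessions with pseudo-random 10 s CS+/CS− cues (balanced
shuffle with at most 3 consecutive same-cue trials, mean ITI 30 or 60 s).
Quantities the source does not report were fixed once at
order-of-magnitude-realistic values and are configurable: transient rate at
rest 0.05 Hz, amplitude 1.0 ± 0.2 ΔF/F, decay τ = 0.6 s (GCaMP6f-like),
additive trace noise SD 0.1, post-event rate gain 4 (positive) or 0.2
(negative suppression — negative modulation is fewer transients, not
negative-going ones) in a 1 s window after the event.

Kinematics: BA is drawn per frame from a two-mode truncated-Gaussian
mixture (rest 0.02 g, movement 0.10 g, each component truncated away from
the midpoint), so bout edges are defined at single-frame resolution and a
histogram-midpoint threshold near 0.06 g is well defined; the norm is
generated first and distributed to three axes by per-frame random unit
vectors, since only the norm enters the analysis.  Transients are
Bernoulli-thinned inhomogeneous Poisson trains at the frame clock convolved
with a 1-frame-rise, exp(−t/τ) kernel (truncated at 6τ) — the rise time of
fast indicators is far below the 67 ms frame period.  Zero-lag coupling:
with probability `shared_coactivation_p` per (optionally masked) trial,
all positively responsive neurons receive one synchronized extra transient
at a shared random latency in the post-event window.  Behavioral event
times for trial-based analyses are aperiodic with a minimum gap
(`generate_event_times`); grid-spaced events would keep a fixed phase
relation under a common circular shift and corrupt shift-based controls.

Movie patches combine footprint × trace somatic sources, a low-rank
spatially correlated background (Gaussian-smoothed white-noise maps with
correlation length `neuropil_corr_len_um`; slow smooth time courses of
characteristic time ~2 s, optionally mixed with a slow-filtered copy of the
summed somatic spike train to emulate neuropil reflecting out-of-focus
activity), and white shot noise.  Trace ensembles with a prescribed
correlation-vs-distance profile are drawn from an eigenvalue-clipped,
re-standardized target correlation matrix; the function returns the
realized (post-projection) correlation as the recovery ground truth — for
the linear profile 0.1 − 2·10⁻⁴·d used in the tests the projection is
numerically a no-op, and the exponential (Matérn-½) kernel used for the
background contrast is PSD exactly.

What the generator does not emulate: biophysical spike-to-fluorescence
nonlinearity, optical PSF and depth blur, motion artifacts, non-stationary
baselines, and behavioral variability structure beyond event timing and
per-trial coupling masks.  Passing recovery tests therefore establishes
the correctness and calibration of the analysis under the assumed
statistical structure, not robustness of the conclusions to real-data
artifacts that upstream steps (motion correction, CNMF-E source
extraction, registration) are responsible for removing.

## Problem sizes and runtime choices

Test and acceptance workloads are sized for a single CPU: bootstrap
calibration uses 200 null neurons × 2,000 shuffles on 30 min sessions;
JPSTH experiments use 12 neurons (66 pairs), 200 trials, 1 h sessions,
averaged over 3 independent sessions for band comparisons; movie patches
are 120 × 120 µm × 8 min at full 1.2 µm resolution with 3 neurons
(full-scale field geometry remains the generator default); the null
distance-regression calibration uses 80 neurons × 100 repeats at 2,000
frames.  Each scripted analysis states the sizes it ran in its output
tables.

## Known limitations

- Negative (suppression) responses are classified reliably from their ETAs,
  but the one-sided area statistic has limited power to detect them; the
  two-sided variant exists for sensitivity analyses.
- The bimodal threshold finder assumes a clear valley; sessions with heavy
  mode overlap require a manually supplied threshold, as in the original
  procedure.
- `pairwise_correlation` returns NaN for pairs with no valid window rather
  than raising; downstream binning drops them.
- The shift-predictor closed form assumes indicator (0/1) trial matrices or
  any fixed per-trial vectors; it is not a Monte-Carlo subset of shifts.
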