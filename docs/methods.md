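# Methods

fluorkit implements the quantitative analyses used to characterise a
GPCR-based fluorescent neuropeptide sensor (an orexin sensor built on the
OX2 receptor with a circularly permuted GFP) from the bench to the awake
cortex: in vitro response and affinity quantification, high-speed
activation kinetics, in vivo fiber photometry around optogenetic and
behavioural events, sleep-state analysis, and a two-photon pipeline that
localises cortical release microdomains. This note records the models,
parameter choices, numerical conventions and limitations.

## Trace normalisation and trial processing

**ΔF/F₀.** `traces.compute_dff` computes (F(t) − F₀)/F₀ with F₀ the mean
over a baseline, given either as a time window or as the *n* samples
immediately before a ligand-addition event (default in vitro convention:
ten points). The baseline must be strictly positive; a non-positive mean
is an error rather than a silent NaN. ΔF/F₀ is dimensionless; multiply by
100 for percent. Whether the "ten points" are raw frames or binned
samples is acquisition-dependent, so the baseline specification is an
explicit argument rather than a constant.

**Binning.** `bin_trace` averages fixed-width bins (100 ms throughout the
in vivo analyses) and drops a trailing partial bin: averaging a short bin
would give it a different noise variance than its neighbours. Bin
timestamps are bin centres.

**Savitzky–Golay smoothing.** Window expressed in seconds (4 s for trial
processing), rounded to the nearest odd sample count; polynomial order
defaults to 3, a common choice when only the window length is prescribed
by the protocol.

**Median-anchored detrend.** Anesthesia makes photometry baselines drift
slowly. `detrend_linear_median` subtracts the line through (median time,
median value) of the first and last 30 s of the trial window. Anchoring
at the median *sample time* (not the nominal window centre) makes a
perfectly linear trace detrend to exactly zero.

**Baseline z-score.** z = (x − median)/s.d. of a 10-s pre-stimulus
window. The protocol wording "s.d. of the median baseline value" is
ill-defined for a scalar; we use the sample s.d. of the baseline-window
values. Sample (n−1) standard deviation is used everywhere an s.d. is
called for; the convention is otherwise unstated. A perfectly flat
baseline (possible only in synthetic data) falls back to median
subtraction at unit scale with a warning, so degenerate trials report
peak 0 and excluded fits instead of crashing.

**Stimulation trials** (`photometry.analyze_stim_trial`). Pipeline on the
[onset − 30 s, onset + 90 s) window: bin 100 ms → Savitzky–Golay →
median-anchored detrend → z-score against the 10-s pre-stimulus window →
peak = max during the laser-on interval (bin centres in
[onset, offset], both edges included). The protocol text calls this
extract "the 130-s sample window" while defining it as 30 + 90 s; the
operative 30/90 numbers are used, giving a 120-s window. The rise is
fitted on [onset, onset + 10 s] after a second 4-s Savitzky–Golay pass;
the decay on [offset, post-offset minimum], smoothed the same way by
default. "Fits that were too poor were excluded" comes with no printed
criterion; the default exclusion rule is non-convergence or r² < 0.5,
configurable via `exclude_below_r2`.

**Event-locked comparison** (tail lifting): means of ΔF/F₀ over the 5-s
pre-event and 10-s event windows, plus the trace normalised by the
pre-event s.d.

**Sleep transitions.** The transition delta is the unsigned max − min of
ΔF/F₀ over the symmetric ±15-s window around a scored transition — the
protocol wording is ambiguous between one straddling window and two
flanking ones, so the two-window variant (|mean_post − mean_pre|) is
available behind `two_window=True`. Transitions within 15 s of a trace
edge are skipped with a warning. Note the max − min statistic is
upward-biased under measurement noise (it includes the noise range); on
noiseless step traces it equals the step exactly.

## Curve fitting

**One-phase exponential association** y = offset + A(1 − e^(−t/τ))
(rise) or offset + A e^(−t/τ) (decay), least squares via
`scipy.optimize.curve_fit`. Initialisation is data-driven — offset from
the first decile, amplitude from the range, τ from the time-to-63% of the
range — and τ is bounded to (0, 10 × duration]. Non-convergence is
reported as a flag with r² = 0, never as NaN parameters.

**Four-parameter logistic** y = bottom + (top − bottom)/(1 + (EC₅₀/x)^h),
fitted on log₁₀(dose). Zero doses are mapped to a pseudo-dose two decades
below the smallest nonzero dose. The parameterisation is degenerate under
(top ↔ bottom, h ↔ −h); fits are canonicalised to top ≥ bottom, so
descending curves carry a negative Hill slope.

## Line-scan kinetics

Dual-channel recordings at 550 Hz: green sensor fluorescence and a
co-applied red dye reporting solution arrival. Pixels are membrane if
their fractional fluorescence change between pre- and post-ligand windows
exceeds `threshold_frac` (default 0.5; the protocol states thresholding
without a number). Trials pass the gate only if the red-dye latency —
from the last near-baseline sample (within 10% of the change) to the
first sample at 85% of the change — is under 50 ms. Membrane-pixel traces
are low-pass filtered with a zero-phase 4th-order Butterworth at 20 Hz
(the protocol specifies low-pass filtering without a cutoff; 20 Hz keeps
>30 samples per τ at the sub-second constants of interest) and fitted
with the exponential association; τ̄ averages converged fits. On
simulations, τ̄ is unbiased within 3% up to 20% amplitude noise, and
gating removes slow-exchange trials whose smeared rises inflate τ.

## Locomotion

The rotary encoder emits a state change per degree; `mm_per_change`
defaults to 2.0 mm. The printed geometry ("around 200 mm" per change) is
inconsistent with both the 11-cm wheel radius (2π·110/360 ≈ 1.92 mm) and
the printed equivalence "65 state changes (13 cm)"; 2.0 mm reproduces the
latter exactly and is treated as the intended value. A bout onset is the
first change following a 1-s window holding ≤ 1 change and followed by
≥ 65 changes within 5 s; candidates are evaluated on raw event times, and
detection is suppressed for 5 s after an onset so one bout is never
counted twice. Onsets in the first second of a recording are not
eligible (quiescence cannot be verified). Speed is state-change counts in
100-ms bins × 2 mm / 0.1 s, in cm/s. Bout metrics take the maxima of the
speed and z-scored (not detrended) fluorescence traces over
[onset + 2.5 s, onset + 5 s]; peak association across bouts is ordinary
least squares with an F test.

## Two-photon microdomain pipeline

Movies are motion-corrected T×H×W stacks (4.9–7.5 Hz, 1.27 µm pixels)
with an anesthetized first minute.

1. **FOV ΔF/F₀**: F(t) is the frame mean over all pixels; F₀ is the
   *median* of F(t) over the anesthetized minute (robust to transients).
   The wake-up effect is summarised as mean ΔF/F₀ of the last minute
   minus the first.
2. **Most-active minute**: per-frame spatial s.d. over pixels, averaged
   over a moving window of n = round(60·frame rate) frames advancing one
   frame at a time inside the search period; ties go to the earliest
   window. The default search period is the 4-min rising phase
   (120–360 s), the stretch between signal onset (~1 min after
   anesthesia off) and plateau.
3. **Binarization**: b(i,j,t) = 1 iff f > median_t(f) + s.d._t(f), per
   pixel over the most-active minute, strict inequality (constant pixels
   never activate). The same window serves as Δt for binarization and
   analysis; a literal "last minute" reading of the protocol is
   reproducible by passing that window explicitly.
4. **Smoothing and deconvolution**: σ = 2 px Gaussian per frame, then
   Richardson–Lucy deconvolution with a 39×39 px, σ = 20 px Gaussian
   kernel, 10 iterations (the referenced implementation's documented
   default). RL is implemented vectorised over the stack with a
   precomputed kernel transform and reflective frame boundaries — a flat
   field is then an exact fixed point — and is cross-checked against
   scikit-image's Richardson–Lucy on interior pixels in the test suite.
   The projection is the deconvolved-frame average.
5. **ROI identification**: percentile bands are computed on the *pooled*
   pixel distribution across all supplied projections (deconvolved
   values are comparable across FOVs). Ten active ROIs live in
   [p70, max], ten inactive in [p5, p69); pixels below p5 (blood
   vessels) belong to no ROI. Placement is greedy and deterministic:
   repeatedly take the highest-valued pixel whose full circle (diameter
   12 px, centred on the pixel corner so an even diameter spans exactly
   12 pixels) lies inside the band and overlaps no accepted ROI. The
   printed "20.4 µm" gloss is inconsistent with 12 px × 1.27 µm
   (15.24 µm); the diameter is a parameter, default 12 px. Shortfalls
   return fewer ROIs with a warning.
6. **Correlations**: Pearson r between raw-fluorescence ROI traces
   (frame means over ROI pixels) during the most-active minute;
   class summaries are mean off-diagonal r among active and among
   inactive ROIs; pairs involving constant traces are undefined and
   excluded.

## Synthetic data

All inputs are generated with seeded pure functions
(`numpy.random.default_rng` keyed by a run seed plus a per-stream label),
and every generator returns the ground truth it embedded. Defaults encode
the acquisition conditions of the analyses they feed: 400-Hz photometry
with a 30-s train, rise 6.77 s, decay 16.31 s, noise 10% of the response
amplitude and a linear baseline drift; 550-Hz line scans with τ = 596 ms,
40% membrane pixels and a 20-ms dye front (an optional mixing-time
parameter slows both the dye front and the sensor rise to exercise the
gate); titrations with EC₅₀ = 75 nM, Hill slope 1, 8 doses log-spaced
over 4 decades and 10% multiplicative noise; cell traces with a ten-point
baseline and a 906% plateau at 5% noise; encoder streams with
quasi-regular in-bout ticks (steady wheel rotation) and Poisson
quiescent ticks at 0.2/s; hypnograms with exponential dwells (wake 120 s,
NREM 180 s, REM 60 s; floor 30 s) and a ΔF/F₀ trace that drops by 0.2 at
REM onset.

The movie generator composes background (100 counts) × (1 + sigmoidal
wake ramp, amplitude 0.3, centred 270 s, width 25 s), 12 Gaussian
hotspots (σ = 7 px, amplitude 150 counts) sharing one bursty latent time
course concentrated in a designated hot minute (150–210 s), Gaussian
noise with variance proportional to the mean (shot-noise-like), and dark
circular vessels (radius 8 px) that are noise-free — blood transmits no
sensor fluorescence — and therefore never cross their own binarization
threshold, which is what places them below the 5th projection
percentile. Hotspots are placed clear of vessel lumina. Default frame
geometry is 256×256 at 5 Hz for 6 min with anesthesia off at 60 s.

What the generators deliberately do not model: photobleaching, movement
artefacts and residual registration error, hemodynamic occlusion
transients, heterogeneous expression across cells, correlated (1/f)
photometry noise, and spatially varying hotspot time courses. Passing
tests therefore demonstrate that the pipelines recover the stated
quantities under controlled, correctly specified conditions — not that
they are robust to every artefact of real recordings.

## Problem sizes and numerical conventions

Stochastic recovery runs use 50 seeded trials (photometry, line scans),
100 titrations and 30 cells; the repeated-movie correlation property uses
20 seeded 96×96, 3-min movies with the same schedule compressed
(hot minute 60–120 s, ramp centred 150 s), while single-movie checks use
128×128, 3.5-min movies and the acceptance script runs the full
256×256×1800 default. Time is float seconds; pixel coordinates are
0-based (row, col); windows are half-open [start, end) except the
laser-on peak search, which includes both edges at bin resolution.
Percentiles use linear interpolation. A known small bias: the fitted
decay constant of stimulation trials runs ~4–6% above truth because the
median-anchored detrend tilts the decay tail and the fit window ends at
the detected minimum; this sits well inside the 10% recovery tolerance
and applies equally to real recordings processed by the same protocol.

## Known limitations

* The ROI placement rule (greedy, brightest-first, full-circle band
  membership) is one deterministic reading of a procedure the protocol
  leaves unspecified; other placements satisfying the same band
  constraints would change which pixels are averaged, though not the
  active/inactive contrast on clearly structured data.
* Richardson–Lucy with a mismatched (much wider than true) kernel is a
  contrast enhancer here, not a calibrated restoration; deconvolved
  values are meaningful only relative to the pooled percentile bands.
* `state_transition_deltas` assumes hypnogram epoch 0 starts at the
  trace's t₀; alignment of independently recorded hypnograms is the
  caller's responsibility.
* The 4PL fit reports the EC₅₀ of the fitted curve; with fewer than two
  doses per decade or asymptotes outside the sampled range its variance
  grows quickly, which is why recovery statements are about medians over
  replicates.
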