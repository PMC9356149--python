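# Methods

This note documents the models, estimators and design choices behind
`erppipe`, in the order the pipeline applies them, followed by the
simulated-data model used for validation and the limits of what the
simulations can show.

## Line-noise removal

Mains interference is modelled as a deterministic sinusoid of slowly
varying amplitude and phase at the target frequency (60 or 50 Hz) plus
optional harmonics. Per channel and per sliding window (default 4 s
window, 1 s step) the data are projected onto K Slepian tapers
(half-bandwidth 2 Hz; K = ⌊2·bandwidth·window⌋ − 1 = 15 at the defaults)
and the complex sinusoid amplitude is the taper-weighted mean value at the
scan frequency. Significance uses the Thomson harmonic F-test with
(2, 2K−2) degrees of freedom. Because the scan takes the maximum F over
the periodogram grid within ±2 Hz, the reported p-value is Šidák-corrected
for the number of scanned bins; a Monte-Carlo null check (white noise)
confirms the corrected test rejects at close to the nominal 1% rate. One
refined scan frequency per channel (parabolic interpolation of the
window-pooled F profile) keeps the per-window phase track coherent; the
complex coefficients are then smoothed across windows with a symmetric
exponential kernel (tau = 100 window steps — effectively a long-memory
average, appropriate for stationary mains) and subtracted only in windows
where the fit is significant (p < 0.01), blended by triangular-weighted
overlap-add. A "legacy" flag disables the smoothing but maps to the same
estimator.

Measured behaviour on a 20 µV sinusoid in unit pink noise: ≥ 50 dB
reduction at the target with < 0.001 dB change at ±5 Hz.

## Bad-channel detection

Four criteria run in order, each on the survivors of the previous one:

1. **Flatline** — a contiguous run with |first difference| < 1e−8 µV
   lasting strictly longer than 5 s.
2. **Spectrum** — per-channel mean log10 Welch power over 1–100 Hz,
   z-scored across channels; flagged if z > +3.5 or z < −5. The pass is
   run twice (flag, drop, re-estimate, flag again; union). The lower bound
   is deliberately lenient so genuinely low-amplitude channels near the
   online reference are not removed. The band stops at 100 Hz because the
   pipeline lowpasses at 100 Hz before detection, so content above it is
   attenuated by construction.
3. **Line ratio** — log ratio of power at line ± 1 Hz to the rest of the
   band, robust z (median / 1.4826·MAD) across channels, flagged above 6.
   Being relative, uniform contamination of all channels flags nothing.
4. **Correlation / predictability** — per 1 s window, a channel's
   agreement with the rest of the scalp, averaged over windows and flagged
   below 0.8. With electrode positions the score is the correlation
   between the channel and its spherical-spline reconstruction from all
   other channels; a best-single-neighbour correlation is also computed
   and the maximum of the two is used, so a bridged/duplicated electrode
   (perfectly matched by its twin) is not flagged while an electrode
   predictable only by the ensemble is still recognised as good. Without
   positions only the best-neighbour route exists. Flagging is greedy —
   the worst sub-threshold channel is removed and scores recomputed — so a
   single grossly aberrant channel cannot drag its neighbours below
   threshold.

On the planted-defect benchmark (20 files × 39 channels; per file one
flat, one ×8-power, one mains-loaded and one decorrelated channel) the
composite detector reaches recall 1.0 at false-positive rate 0.0.

## Wavelet artifact correction

Each channel of the continuous record is decomposed with a stationary
(undecimated) coiflet-4 transform to L = round(log2(rate)) − 1 levels, so
the coarsest detail band reaches ≈ 1 Hz; the signal is reflection-padded
to a power-of-two length first. Artifact is defined as supra-threshold
coefficient content: per level, λ_j = σ_j √(2 ln N), and the coefficient
is split into a retained part (|w| ≤ λ, or clipped to ±λ in soft mode) and
an artifact part. Soft mode shrinks — gentler, best for already-clean
data; hard mode removes entire outlying coefficients — more aggressive
under heavy or variable artifact. The approximation band (< ~1 Hz) is left
untouched by default; its slow residuals are handled downstream by the ERP
highpass and baseline correction (thresholding it as well is available and
makes isolated large transients almost perfectly localised).

The scale σ_j is a Gaussian-consistent robust estimate taken at the 90th
percentile of |d_j| (q90 / 1.2816). On Gaussian background this equals the
familiar MAD/0.6745 estimate, but it remains calibrated when genuine
oscillatory signal occupies a sizeable duty cycle of a band: a pure
median-based scale collapses on sparse noise-free signals and would
misclassify a clean evoked train as artifact. Verified: a noise-free VEP
train passes soft thresholding with correlation > 0.999 and < 0.1% N1
change, while a 500 µV, 100 ms square pulse is removed > 80% (> 99% with
the approximation thresholded too) with sub-µV RMS disturbance beyond
200 ms from the pulse.

Exact additivity (cleaned + removed = input, ≤ 1e−6 µV) holds by linearity
of the inverse transform and is asserted in tests.

## Filters

The FIR path is a Hamming windowed sinc applied as a centred symmetric
convolution (exactly zero phase). The order is estimated from the
transition width tb = min(max(0.25·f_edge, 2 Hz), f_edge), taps =
⌈3.3·rate/tb⌉ rounded to odd; reflection padding is capped at N−1 samples
when kernels exceed the data length. The IIR path is a Butterworth applied
forward-backward over second-order sections; the nominal order rule
3·⌊rate/highpass⌋ produces orders in the thousands for ERP-range cutoffs
(rate 1000, highpass 0.1 → 30 000), which is numerically meaningless, so
the design order is capped at 8 (lowpass-only designs use order 4). A
fixed 100 Hz lowpass precedes artifact and bad-channel detection so those
steps see only the neural band.

## Segmentation, repair, rejection

Epoch windows are half-open in samples, mapped by round(ms·rate/1000) and
shifted by the user's timing offset; events whose epoch would leave the
recording are dropped and counted. Baseline correction subtracts the
per-trial per-channel mean over the baseline window. Within-segment repair
computes the four FASTER statistics per (trial, channel) — variance,
median absolute successive difference, amplitude range, deviation from the
channel grand mean — z-scored per channel across trials; any |z| > 3 flags
the pair, which is then re-estimated by spherical splines from that
trial's clean channels (trials with fewer than four clean channels are
marked for rejection instead).

Segment rejection marks, never deletes. The amplitude criterion flags a
trial when any evaluated channel leaves [−150, +150] µV (bounds
configurable; the literature convention for developmental data is ±200).
The joint-probability criterion estimates each channel's sample density as
a 256-bin histogram with add-one smoothing over samples pooled across
trials; a trial-channel score is the sum of log densities of its samples.
The single-electrode route z-scores this across trials per channel; the
electrode-group route z-scores the trial-normalised scores across
electrodes within the trial (normalising first is what makes a perfectly
homogeneous file produce no rejections — raw cross-electrode scores differ
between channels for benign reasons). Either |z| > 3 marks the trial; all
marks are applied in one step. Restricting evaluation to an ROI can only
retain more trials, which is asserted as a property.

## Spherical-spline interpolation and re-referencing

The interpolation kernel is g(cosθ) = (1/4π) Σ_{n=1..7} (2n+1) /
(n⁴(n+1)⁴) P_n(cosθ) — seven Legendre terms, stiffness m = 4 (the standard
scalp-potential choice) — with a 1e−5 ridge on the diagonal and a constant
term, making the estimate linear in the data and exact for constant
fields. A degree-1 harmonic field is reproduced to < 5% RMS on a
32-channel montage. Re-referencing subtracts the mean of all channels or a
subset; when a prior online reference is known, a zero channel under its
name is appended first so its signal is recovered. If the montage lacks a
position for that channel the montage is cleared rather than left
inconsistent.

## Quality reports

The data-quality table has one row per file with the exact column set
(FileName, File_Length_s, Number_Segs_Pre-Seg_Rej,
Number_Segs_Post-Seg_Rej, Percent_Good_Chans_Selected,
Interpolated_Chan_IDs, Percent_Var_Retained_Post-Wav, ICA_Metrics,
Chans_Interpolated_Per_Seg); ICA metrics are always "NA" on the ERP path
and per-segment interpolation shows "N/A" when disabled. Percent variance
retained is the channel mean of 100·(1 − var(pre−post)/var(pre)) — large
removals can drive it strongly negative, which is informative, not an
error. The pipeline-quality table reports pre/post correlations band-
limited to f ± 1 Hz (proportional, [f/2, 3f/2], below 2 Hz) at the line
frequency ± 1…5 Hz and at 0.5, 1, 2, 5, 8, 12, 20, 30, 45, 70 Hz plus
broadband, each the median across channels. Successful line removal shows
a dip at the target only.

## ERP measures

Waveforms are means over kept trials then selected channels; grand
averages carry per-timepoint SE (sample SD/√n) and 95% CI (±1.96 SE).
Peaks are windowed extrema with the user's polarity, earliest sample on
ties; global extrema and all local extrema are also listed. Window bounds
are inclusive after round() mapping. Zero-crossing windows place
boundaries at the axis ends, at each exact zero sample and at the first
sample after each sign change, and provably partition the axis. Signed
AUC is trapezoidal in µV·ms; the global AUC integrates |values| over the
whole post-stimulus waveform; the 50%-area latency is the first timepoint
where the cumulative |area| in the window reaches half the window total
(absolute values inside the window, consistent with the global-absolute
convention). Peak-to-peak values are current minus prior component
(N1→P1 gives a positive N1-P1).

## Simulated data

The VEP train is 60 epochs of 500 ms at a configurable rate (default
1000 Hz; the benchmark harness runs at 250 Hz to keep batch runs light —
all results quoted here are at 250 Hz unless noted). Components are
Gaussians with σ = width/6 on the epoch-time axis (centers 170/200/235 ms;
the first 100 ms is the pre-stimulus baseline, and the standard N1/P1/N2
measurement windows 150–190/180–220/215–255 ms are quoted on the same
axis). Amplitudes progress linearly across the train from A to A + slope —
the simplest reading of an "amplitude slope" over trials. The summed
base-amplitude waveform has its N1 minimum at −7.4217 µV, the anchor value
for calibration; the trial-average truth (slope midpoint) is −8.296 µV at
250 Hz.

The synthetic resting-EEG background is built from 12 pink-noise (1/f)
sources projected through smooth scalp topographies — wide Gaussian
patches on the unit sphere (concentration κ = 3), centred across channels
— plus 10% independent pink sensor noise, scaled to 10 µV RMS per channel
(a "relatively artifact-free" developmental recording). The centred,
smooth fields encode two physical facts: volume conduction makes
neighbouring electrodes strongly correlated, and dipolar potentials
largely cancel in the scalp average. The latter is why all-channel ERP
averaging sees very little background leak-through and the clean-embedding
check recovers peaks to well under 2%.

The artifact battery adds, with a seeded generator: blink transients
(400 ms raised cosine, frontally weighted, 15/min, per-event amplitude
uniform in 0.3–1 × 280 µV — real blinks vary, and the sub-threshold ones
are precisely what correction must handle since rejection cannot), EMG
bursts (20–45 Hz band-limited noise, 1 s, laterally weighted, 60 µV,
12/min), slow drift (lowpassed random walk, 60 µV) and residual mains
(10 µV, 60 Hz). Severities were chosen so that, without correction,
roughly a tenth to a fifth of trials cross the ±150 µV bound — the
artifact load of a visibly contaminated developmental file.

The recovery benchmark processes 16 clean and 16 artifact-added files
(same underlying EEG per pair) through line-noise removal → hard wavelet →
0.1–35 Hz FIR → segmentation → baseline correction. Morphology and SE are
evaluated on trial-matched data, i.e. before any segment rejection, so
they isolate the artifact-correction step; trial retention under ±150 µV
is tallied separately. Typical results: clean-vs-artifact N1 gap well
under 10% (usually < 4%), across-file SE 10–35% lower with correction than
without in the artifact condition, and higher trial retention with
correction.

### What the simulations do not show

The background model is spatially smooth, stationary and Gaussian-ish; it
has no alpha rhythm, no non-stationary state changes, no electrode
drift-and-pop behaviour, and its artifact classes are parametric
idealisations rather than real ocular/myogenic topographies. Passing the
benchmarks therefore demonstrates the machinery is correct and the
artifact-correction logic behaves as designed under controlled load — it
does not certify performance on any particular real dataset, and the
bad-channel benchmark's perfect score reflects cleanly planted defects,
not the ambiguity of real marginal channels. Thresholds shipped as
defaults (±3.5/−5 SD, ratio 6 SD, correlation 0.8, flatline 5 s, ±150 µV)
come from the published empirical optimisation on real EEG and are kept
verbatim.

## Numerical conventions

Internal sample indexing is 0-based; user-facing quantities are in
seconds/ms/µV. Millisecond-to-sample mapping is round(ms·rate/1000)
everywhere. Event onsets are integer samples. All randomness flows through
explicit `numpy` generators seeded by the caller; identical seeds give
byte-identical synthetic data. Degenerate inputs are guarded: zero-SD
z-scores are defined as 0 (so homogeneous data flags nothing), zero-variance
channels are excluded from variance-retained means, and an empty epoch set
is a noted result, not an exception.
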