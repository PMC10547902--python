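# Methods

This note documents the models, estimators and design choices behind
the package, in the order the pipeline runs.

## Synthetic sessions

The generator exists so that every downstream stage can be tested
against known ground truth. A session alternates resting blocks with
cry and distress episodes; audio (48 kHz, 24-bit WAV), 8-channel EEG
(512 Hz), NIRS (one sample / 2 s) and per-episode COMFORT scores share
one clock, with tab-separated condition annotations.

**Cry units** use a source–filter model: a glottal pulse train whose
pulses are placed at fractional-sample positions with windowed-sinc
kernels (so the programmed periods are exact; integer-sample rounding
alone would add an apparent jitter of order 1/(T·fs) ≈ 0.005 at
700 Hz, larger than the round-trip tolerance), per-cycle multiplicative
period perturbation for jitter and amplitude perturbation for shimmer
(Gaussian, scaled by √π/2 so the *expected measured* local statistic
equals the requested value), a cascade of three two-pole resonators at
F1–F3 (default bandwidths 450/500/550 Hz — wide, as in tense neonatal
phonation; wide bandwidths also keep consecutive cycles nearly
non-overlapping, which the HNR estimator relies on), and white
Gaussian noise whose power is set from the measured clean-signal power
so the harmonic/noise ratio equals the requested HNR exactly in
expectation. That analytic ratio is the oracle for all HNR tests.
No extra glottal spectral tilt is applied: the flat-source spectrum
keeps enough high-frequency energy for cycle timing to reach the
round-trip jitter tolerance at low HNR (the timing error of a
matched-filter estimator scales as 1/(RMS bandwidth · √SNR)).

**Condition profiles** default to the published group statistics for
the two cry classes (cry: F0 477.6 ± 109.4 Hz, jitter 0.016, shimmer
0.113, HNR 11.9 dB, formants 1429/3558/5897 Hz; distress: 412.6 Hz,
0.022, 0.143, 6.7 dB, 1631/3740/6095 Hz). Episodes default to ~30
units (≈ 40–50 s), matching observed cry-bout structure with a voiced
fraction near 0.6 (cry) / 0.65 (distress). EEG and NIRS generative
magnitudes are *not* published; the defaults are calibrated only to
reproduce orderings: delta oscillator power falls and theta/alpha rise
from resting through distress; PR rises and SpO2/rSO2 fall. COMFORT
item means are 1.5 / 3.0 / 4.5 for resting / cry / distress.

Each episode carries a latent arousal z-score that jointly lengthens
units, shortens gaps, raises PR (+8 bpm/SD), lowers rSO2/SpO2 and
shifts COMFORT items, reproducing the qualitative cross-modal
correlation structure (PR positively and rSO2 negatively correlated
with cryCE) without asserting any particular effect size.

EEG channels mix a shared and a channel-specific source (60 % shared
variance) to mimic volume conduction; fully independent channels would
be flagged by the decorrelation bad-channel rule. What the generator
does **not** emulate: perceptual realism of cries, movement/muscle EEG
artifacts with realistic spectra (bursts are simple 500 µV humps),
respiratory or circadian NIRS dynamics, or inter-rater COMFORT
disagreement. Passing tests therefore certify the *pipeline
machinery*, not clinical validity on real recordings.

## Acoustic estimators

**Segmentation.** Frames of 40 ms / 10 ms hop are cry-active when
short-time energy exceeds −40 dB relative to the loudest frame *and*
the 200–1200 Hz band-passed normalised autocorrelation peaks at
≥ 0.45 in the pitch lag range. Sub-60 ms dips are closed, runs
shorter than 200 ms discarded, and gaps longer than 5 s split
episodes (the episode-boundary rule is otherwise unspecified in this
analysis style).

**F0.** Band-pass 200–1200 Hz, frame-wise unbiased normalised
autocorrelation, lag search restricted to 40–240 samples at 48 kHz,
parabolic lag refinement. Two guards matter in practice: among
autocorrelation peaks within 0.15 of the maximum the *shortest* lag
wins (suppressing octave errors, which otherwise contaminate the mean
at high F0 and low HNR), and a frame is voiced only if the *raw*
waveform also shows ≥ 0.30 autocorrelation at the same lag —
band-limited noise alone is locally self-similar inside a narrow band
and would otherwise pass.

**Cycle measures (jitter, shimmer, HNR).** Praat-style fixed-lag
frame autocorrelation is biased whenever the period itself fluctuates:
period jitter decorrelates cycles at any fixed lag, so HNR reads low
and the bias grows with exactly the quantity (jitter) being measured.
The package instead works cycle-synchronously. Marks are peaks of the
band-passed waveform; each cycle window (0.95 median periods, starting
0.1 window-lengths before the mark so the previous cycle's decay tail
contributes as little as possible) is aligned to the mean cycle
template of a low-passed (8 kHz) copy by unnormalised cross-correlation
with sinc-interpolated peak refinement — correlation sequences of
sampled signals are band-limited, so sinc interpolation recovers the
continuous peak without the bias of a three-point parabola. Periods
are differences of consecutive aligned event times; periods deviating
more than 20 % from a running median are mark artifacts and dropped.
Amplitudes are aligned projections onto the unit-norm template (robust
to additive noise at the √(window length) rate). HNR uses the
normalised correlation between consecutive *raw* cycles, evaluated
*at* the timing-derived lag rather than maximised over lags
(maximising picks the upper tail of the correlation's sampling noise
and biases HNR up by ~1 dB at HNR 0), averaged and mapped through
10·log10(r/(1−r)), clipped to [−10, 40] dB.

The measured jitter additionally carries a predictable timing-noise
floor: the per-event matched-filter error is σ_n/(α·‖u′‖) (α the
template correlation peak, u the unit-norm template), a second
difference of event times has variance 6σ_t², and Gaussian components
add in quadrature. The estimator subtracts this floor in quadrature,
which centres the estimate at zero true jitter and removes a small
upward bias elsewhere; without the correction the floor at
F0 = 700 Hz and HNR = 5 dB (≈ 0.007) exceeds the 0.005 round-trip
tolerance — and that floor is the information-theoretic limit of the
signal, not an implementation artifact.

**Formants.** Frame-wise linear prediction is unreliable at infant
F0 (350–700 Hz): the spectral envelope is only sampled at harmonic
multiples of F0 and all-pole fits lock onto individual harmonic lines
(observed errors of 10–60 %). The package fits the source–filter
magnitude model directly in the harmonic domain: the unit is
low-passed at 10 kHz, resampled to 20 kHz, Welch-averaged, and reduced
to one *integrated* energy per harmonic (±0.45 F0 — integration makes
the sample invariant to the line broadening caused by jitter and F0
contours, which otherwise tilts the sampled envelope). A model with a
gain, a spectral-tilt term, a noise floor (log-sum-exp) and three
Lorentzian resonance pairs with half-widths bounded in [75, 400] Hz is
fit to the log energies by robust (soft-L1) least squares from four
starting layouts spanning the plausible newborn formant space
(F1 ∈ [0.9, 2.2], F2 ∈ [2.2, 4.3], F3 ∈ [4.3, 9] kHz); the best fit's
sorted resonance centres are F1–F3. Units without voiced frames or
with fewer than six usable harmonics return missing values. On the
generator's round-trip grid this recovers all three formants within
5 % where LPC failed badly; the worst case observed (rise–fall
contour, F0 700 Hz, jitter 0.03, HNR 5 dB) errs by ~8 % on F1.

**MFCC / spectrogram.** 40-mel filterbank (50 Hz–Nyquist), log, DCT-II
(orthonormal), first 13 coefficients; the per-unit summary is the
frame-wise mean and SD (26 values). Amplitude scaling moves only the
0th coefficient, because a gain multiplies every mel energy and the
constant log offset projects onto the DC basis vector alone. The CNN
input is a 64-mel × 59-frame log-mel image (1.5-s centre pad/crop,
50 ms windows, 25 ms hop), standardised per image.

## EEG

Order of operations: bad-channel detection → spherical-spline
interpolation (only if exactly one channel is bad; more rejects the
recording) → 1–45 Hz zero-phase Butterworth band-pass → average
reference over good channels → 4-s epoching within condition intervals
→ amplitude rejection. The band-pass is order 12 (flat 1.5–44 Hz,
≈ −25 dB at 50 Hz after forward–backward filtering), steep enough to
place 50 Hz mains more than 20 dB down, which a conventional 4th-order
design does not achieve. The decorrelation bad-channel rule only
applies when the montage's median inter-channel |correlation| itself
exceeds the threshold — on an uncorrelated recording the rule is
meaningless and would flag everything. "Average amplitude < 200 µV" is
operationalised as the channel-mean of per-channel peak absolute
amplitude per epoch.
Spherical splines use the Legendre-series g function with order m = 4,
7 series terms and a 10⁻⁵ ridge, on idealised unit-sphere 10–20
electrode positions shipped as a constant table. Welch uses 1-s
Hamming windows with 50 % overlap so bins are 1 Hz wide and band edges
fall on bin centres, and no per-segment detrending (mean removal leaks
through the window mainlobe into the 1 Hz bin and biases delta power a
few percent low; the band-pass has already removed DC); bands are
half-open [lo, hi) so the 4 and 8 Hz bins are counted exactly once. Relative power is band power over total
1–45 Hz power (44 one-hertz bins — a flat spectrum gives 3/44, 4/44,
4/44 for δ/θ/α); percent change is 100·(cond − resting)/resting on the
per-(channel, band) means.

## NIRS

The flat-line rule uses a centred 60-s rolling window per variable in
native units, and a sample is removed when *any* window containing it
falls below the 0.5 SD threshold (the centred low-SD mask dilated by
the window half-width) — this excises whole dropout runs including
their edges; keeping the edges would leave a point mass of repeated
values that poisons the quantiles downstream. The 1.5·IQR fences are
computed over the whole SD-cleaned recording (not per segment), are
skipped when the spread is degenerate (IQR = 0), and both rules
iterate to a fixed point, which makes the cascade idempotent by
construction; on clean Gaussian data total removal stays under 1 %. Segmentation assigns a sample
whose 2-s acquisition window lies strictly inside (start + 15 s,
end − 15 s); a 60-s interval on the 2-s grid therefore retains 14
samples and a ≤ 30-s interval none. Floor comparisons are strict, so
a segment mean exactly at 80 / 50 / 70 is retained.

## Statistics

Mann–Whitney (exact for small tie-free samples), Kruskal–Wallis and
one-way ANOVA delegate to scipy; Holm–Bonferroni to statsmodels.
Dunn's test uses pooled-rank z statistics with the ∑(t³−t) tie
correction and Holm adjustment within the family of pairs. The
bootstrap Tukey–Kramer null resamples mean-centred observations within
groups (10,000 draws by default) and refers each pairwise studentised
range to the null distribution of the *maximum* q, preserving
family-wise control without normality. Kendall W uses the
tie-corrected formula 12·S / (m²(n³−n) − m∑T). The concordance report
treats each (audio feature, partner feature) pair as m = 2 rankers
over a condition's episodes — the reading consistent with one W per
feature pair — so W = (ρ_spearman + 1)/2; note that under independence
W then scatters around 0.5, which is why only the W > 0.7 flag is a
meaningful rarity under the null.

## Classifier

The random forest (500 trees) runs on MFCC summaries; the CNN on
spectrogram images is a NumPy implementation (im2col convolutions,
batch normalisation, 2×2 max pooling, one 64-unit dense layer, Adam,
early stopping on validation loss with patience 2). The 80/20 split
is a plain random split with the remainder to training
(ceil(0.8·1964) = 1572 / 392), unstratified; an optional group-wise
split was considered and rejected because synthetic units carry no
subject identity. Distress is the positive class, so sensitivity
measures distress detection. Training is seed-deterministic; CNN
metrics are treated as stochastic with a tolerance band in tests.
The synthetic two-class problem is considerably easier than real
cry data (no environmental noise, no annotation ambiguity), so
validation accuracies near 1.0 are expected and the ≥ 0.90 check is a
machinery test, not a clinical claim.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately compact problem sizes chosen
as the package's own defaults: the round-trip grid uses 1.2-s units
(≈ 400–800 cycles each); EEG direction checks use 295 balanced 4-s
epochs per condition; classifier checks use 1,000 synthetic units
(800 train / 200 validation) and a label-shuffled control; bootstrap
tests in the unit suite reduce repetitions to 1,500 while the
configured default stays 10,000. Degenerate inputs (silence, white
noise, all-unvoiced units, empty segments, single-class training sets)
return missing values or raise typed errors rather than guessing.

## Known limitations

- Formant recovery degrades toward ~8 % error for strongly contoured,
  low-HNR, high-F0 units; bandwidth estimates are not reported at all.
- The jitter noise-floor correction assumes Gaussian timing errors and
  white additive noise; coloured noise would change the floor.
- The concordance analysis inherits the m = 2 interpretation; W values
  near 0.5 are uninformative under it.
- EEG artifact handling covers amplitude bursts and flat channels
  only; ocular/muscle artifact subspace removal is out of scope.
- All validation is against the package's own generator; none of the
  numeric tolerances transfer to real recordings without new
  calibration.
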