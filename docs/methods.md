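# Methods

`eegbico` analyzes ongoing multichannel EEG for two kinds of structure —
band-limited oscillatory power and cross-frequency quadratic phase
coupling — and estimates behavioral mechanical-withdrawal thresholds from
up-down staircase data. This note describes the models, the estimators and
their numerical choices, the synthetic data the package validates itself
on, and the limits of what those validations show.

## Signal conditioning

Recordings (channels × samples, µV) are processed in a fixed order:
band-pass filter → average rereference → channel rejection → epoching
(→ optional epoch-level artifact rejection). The order matters because the
average reference mixes channels: filtering first keeps out-of-band
artifacts from leaking across channels through the reference.

**Band-pass (default 1–45 Hz).** Zero-phase (forward–backward) elliptic
filter sized by `scipy.signal.ellipord` for ≤ 0.2 dB single-pass passband
deviation and ≥ 25 dB single-pass stopband attenuation, stopband corners
at 0.3 × lo and (50/45) × hi. After the forward–backward pass this gives
< 1 dB ripple across [lo+1, hi−1], ≥ 50 dB at 50 Hz mains for the default
band, and enough DC rejection that a 100 µV offset leaves a sub-µV mean.
A low fixed-order Butterworth cannot satisfy these constraints
simultaneously (a 4th-order design leaves 50 Hz attenuated by only ~7 dB
while already losing 6 dB at 44 Hz), hence the elliptic design.
Zero-phase filtering is essential: bicoherence measures phase relations,
and a causal filter's frequency-dependent phase delay would distort them.

**Average rereference.** Each retained channel minus the mean of retained
channels; excluded channels neither contribute to the mean nor appear in
the output. The operation is an idempotent projection (retained channels
sum to zero at every sample).

**Channel rejection.** Offline stand-in for acquisition-time quality
control: peak-to-peak amplitude above `amp_limit` (default 1000 µV) or
below `flat_limit` (default 0.01 µV) removes a channel, with the reason
recorded. Electrode impedance is not available offline, so an amplitude
criterion replaces it.

**Epoching.** Half-open integer-sample windows [start, start + L), step
L(1 − overlap); defaults 2 s and 75% overlap, giving
floor((N − L)/step) + 1 epochs with no resampling drift. Inputs at other
rates are polyphase-resampled to the analysis rate (default 256 Hz) first.
Movement artifacts / baseline drift are handled by epoch rejection: an
epoch whose peak-to-peak exceeds a configurable multiple (default 6×) of
the median is dropped. This is a pragmatic rule, not a reconstruction of
any particular artifact-removal algorithm.

## Morlet wavelet power

Power spectra use a complex Morlet wavelet with central angle frequency
ω = 6 cycles on a 1–45 Hz grid in 0.5 Hz steps. The transform is computed
in the frequency domain (Gaussian kernels, epochs zero-padded to twice
their length so wavelet tails cannot wrap around) and **normalized to unit
gain at the analysis frequency**: a sinusoid of amplitude A reports its
mean-square power A²/2 at every frequency. This makes peak powers directly
comparable across frequencies and exactly quadratic in amplitude. (The
common L2 normalization instead weights a sinusoid's response by 1/f,
which would make cross-frequency amplitude comparisons scale-dependent;
for white noise the two conventions differ only by a smooth frequency
weighting.) A cross-check against PyWavelets' `cmor` implementation, gain
differences accounted for, is part of the test suite.

**Cone of influence.** Within each epoch, samples closer than 2σ_t to an
edge are excluded from the time average, σ_t = ω/(2πf) being the wavelet's
Gaussian time-std. At 1 Hz, 2σ_t ≈ 1.91 s — more than a 2-s epoch — so the
margin is capped so at least two central samples survive. Consequence:
delta-band estimates from 2-s epochs rest on few effective samples and
carry wide variance; treat single-epoch delta power as indicative only
(session averages over many overlapping epochs are much tighter).

**Aggregation and bands.** Power is averaged over time within an epoch,
then across epochs. Band powers average the spectrum over in-band grid
points for delta 1–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz;
a grid point on a shared endpoint belongs to the upper band (gamma is
closed at 45 Hz) so nothing is double-counted. Relative power divides by
the five-band total, so each channel's relative values sum to 1; the
"overall power" normalizer is the analyzed 1–45 Hz range, not any
unanalyzed frequencies. Session change is reported as
(After − Before)/Before × 100% per channel and band, with zero-baseline
cells flagged NaN rather than dropped.

## Wavelet bicoherence

Quadratic phase coupling — φ(f₁+f₂) = φ(f₁) + φ(f₂) — is measured with
harmonic (box-spectrum) wavelets: for each center frequency on a 1–45 Hz
grid (1 Hz step), the FFT bins within a 2 Hz band are retained (negative
frequencies zeroed) and inverse-transformed into a complex analytic series
W(f, t) per epoch. The squared-normalized bicoherence

    b²(f_j, f_k) = |⟨W_j W_k W*_{j+k}⟩|² / (⟨|W_j W_k|²⟩ ⟨|W_{j+k}|²⟩)

pools time samples and epochs in a single average ⟨·⟩ (maximum estimator
stability for session-length data), lies in [0, 1] by Cauchy–Schwarz, is
invariant to amplitude scaling, and is computed only on the principal
domain f_k ≤ f_j, f_j + f_k ≤ 45 Hz. Cells whose sum frequency would
exceed the grid cap simply do not exist on the truncated domain; band
pairs with no valid cell (gamma–gamma under a 45 Hz cap) return NaN, a
sentinel distinct from true zero coupling. At least two epochs are
required (the normalization is degenerate on one).

**Significance filtering.** The "filtered" coupling value zeroes cells
below a threshold. The principled mode builds the threshold from
surrogates: the channel's continuous signal is reconstructed from its
contiguous overlapping epochs, Fourier phases are randomized independently
within each non-overlapping epoch-length block, and the surrogate is
re-epoched with the original overlap. Two details matter. (1) Randomizing
per overlapping epoch would break the sample-sharing between epochs and
understate the null — 75% overlap inflates the real estimator's variance
roughly fourfold relative to independent epochs. (2) Randomizing the whole
signal in one pass would leave every FFT bin's phase constant in time, and
a stationary sinusoid triplet has constant φ₁+φ₂−φ₃ regardless of its
phases — its bicoherence would survive the surrogate, defeating the test.
Blockwise randomization of the reconstructed signal avoids both. Default:
40 surrogates, per-cell 95th percentile. With finitely many surrogates the
realized false-positive rate sits somewhat above the nominal 5%, but the
false positives are near-threshold values far below genuine coupling. A
fixed scalar threshold mode exists for cheap exploratory filtering; when
epochs are not contiguous (after epoch rejection) the code falls back to
per-epoch randomization and records it.

**Band-pair totals.** The total coupling between two canonical bands sums
the stored values over principal-domain cells whose frequencies fall in
the (symmetrized) band pair. Because the stored values are already the
squared-normalized statistic, the default sums them as-is; a `square=True`
flag instead squares before summing, for the convention in which stored
values are magnitudes. All internal tests state which convention they use.

**Statistical unit.** Group comparisons of coupling use one value per
animal — the channel-averaged band-pair total — never per-channel or
per-epoch values, so sample sizes in tests equal the number of animals.

## Session statistics

Paired t (within-group session changes), Welch unpaired t (between
groups; pooled optional), and Wilcoxon rank-sum (coupling comparisons),
all two-sided at α = 0.05. The rank-sum p-value is exact for combined
n ≤ 20 without ties and a tie-corrected normal approximation otherwise,
with the method recorded. Degenerate inputs (zero-variance differences,
all-identical pooled samples) raise explicit errors instead of returning a
number. Per-channel significance screens report uncorrected p < α —
matching how per-electrode maps are conventionally reported — with an
optional Benjamini–Hochberg mode that is always recorded in the output.

## Topography

Per-electrode values are interpolated over the planar montage by
barycentric linear interpolation on the Delaunay triangulation: exact at
electrodes, bounded between the extreme electrode values, no extrapolation
beyond the convex hull (a thin-plate spline option exists but may
overshoot). The packaged 14-label rat epidural montage carries the twelve
scalp positions plus reference/ground rows; the reference/ground
coordinates assume a 9 mm bregma–lambda distance (stated in the file) and
are excluded from maps. The printed source coordinates are ambiguous for
the centrofrontal group ("A ±1.5 mm"); the fixture resolves FL2/FR2
anterior and PL1/PR1 posterior. Maps are qualitative: no quantitative
result is read off interpolated colors.

## Up-down withdrawal threshold

The staircase uses the eight-filament ladder 0.41, 0.70, 1.20, 2.00, 3.63,
5.50, 8.50, 15.10 g, whose mean log10 spacing is δ = 0.224. After a
withdrawal the next weaker filament is presented, after no response the
next stronger; at a ladder boundary the boundary filament repeats; the
staircase ends six stimuli after the first response change. The estimate is

    PWT50 = 10^(X_f + k δ) / 10⁴  grams,

with X_f = log10 of the last force in 0.1 mg units — the only convention
under which the 10⁴ divisor returns grams, so k = 0 reproduces the last
filament exactly. The correction k is read from a packaged table indexed
by the terminal response pattern (the response before the first change
plus the seven that follow; 128 patterns). **The table is generated by
this package**, not copied from any published tabulation: for each pattern
the filament trajectory is reconstructed and k is the maximum-likelihood
threshold of a probit model with σ fixed at one ladder step, expressed in
steps relative to the last filament (`build_k_table()` regenerates it).
This is Dixon-style in spirit; its values are validated against the
formula's arithmetic and against simulated responders, not against any
printed table. Perfectly alternating staircases give k = ∓0.5, i.e. the
log-midpoint of the two visited filaments. Sequences that never change
response are reported as censored bounds (≤ 0.41 g / ≥ 15.10 g), and
interior estimates falling outside the ladder are clamped and flagged.
Simulated responders are logistic in log10(force) (deterministic step in
the infinite-slope limit), matching the log-spaced ladder.

## Synthetic data

The generator produces what the analysis needs to be testable with known
ground truth, from a single seed (NumPy `SeedSequence`-derived streams):

* **1/f^slope background** by FFT-domain amplitude shaping of white noise
  (exact slope control), renormalized to a target RMS per channel.
* **Band-limited components** by zero-phase narrow-band filtering of white
  noise, rescaled to exact RMS on selected channels.
* **QPC triplets**: sinusoids at f₁, f₂, f₁+f₂ where the sum component's
  phase equals φ₁+φ₂ on a fraction *s* of 2-s segments — one contiguous
  locked episode of round(s · n_segments) segments at a random position —
  and is randomized per segment elsewhere. Contiguity matters: scattering
  the locked segments would put a phase discontinuity at nearly every
  segment boundary, and each discontinuity corrupts the sum-band wavelet
  phase over its ~0.5 s time resolution, pushing low strengths into the
  estimator's null floor. With the contiguous episode the time-pooled
  bicoherence magnitude approaches *s* (squared statistic ≈ s²).

**The incision/treatment study** (`eegbico.studies`) fixes three session
conditions per simulated animal: a delta-dominant baseline; a
post-incision state with the delta component attenuated, theta/alpha/beta
strengthened (partly via added coupled triplets with sums at 10, 16, 23,
25 Hz), the gamma component untouched, and total power held roughly
constant so the unchanged gamma also stays unchanged in *relative* terms;
and a post-treatment state with the beta component restored to baseline
and the beta-sum triplets removed. Component RMS values are jittered
lognormally (σ = 0.15) per animal and session to emulate
session-to-session state variability — without it, between-animal variance
would be estimation noise only and arbitrarily small shifts would reach
significance. Effect sizes are fixed so that every effect the study design
declares (delta ↓, theta/alpha/beta ↑, treatment reversal of beta power
and beta–low-frequency coupling) is decisively detectable at n = 8, as
befits conditions meant to embody clearly significant findings, while the
gamma band stays non-significant.

**What the synthetic data does not contain:** cortical source geometry and
volume conduction (channels are statistically independent up to the
shared condition parameters), stimulation artifacts, non-stationary
arousal dynamics, heavy-tailed artifact distributions, or line noise.
Passing the packaged studies therefore demonstrates correctness of the
estimators and the direction-recovery logic under controlled conditions —
not robustness to every pathology of real recordings.

## Problem sizes

The packaged validation studies run at desk scale by choice: 60-s sessions
(117 overlapping epochs) for the three-session study, with bicoherence on
a four-channel subset — the band-pair statistic is channel-averaged per
animal, so the subset changes cost, not the statistical unit — and the
unfiltered statistic for the group comparison (the surrogate filter is
validated separately; it sharpens, but is not required for, the direction
contrast). Coupling-recovery checks use 200 epochs and single channels.
Session-length recordings (25–30 min) run through the identical code
paths; only the constants differ.

## Numerical details worth knowing

* Epoch boundaries are integer sample indices; epochs are copies, never
  views.
* Bicoherence accumulates over epoch blocks (64 at a time) to bound
  memory; Morlet power chunks over channels and frequency blocks for the
  same reason.
* `nan` is the sentinel for "undefined" throughout (outside the principal
  domain, empty band pairs, zero-baseline change rates); errors are raised
  only for contract violations.
* EDF output is 16-bit with per-channel physical scaling (quantization
  ≤ peak/2¹⁵); reading goes through MNE and returns µV.
* All randomness — synthesis, surrogates, simulated responders — descends
  from explicit integer seeds; rerunning any pipeline with the same config
  and seeds reproduces every table byte-for-byte.

## Known limitations

* Delta-band power from 2-s epochs is high-variance (see cone of
  influence); prefer longer epochs if delta is the quantity of interest.
* The surrogate filter's realized false-positive rate exceeds the nominal
  α because the per-cell threshold is a finite-sample quantile estimate
  (40 surrogates); survivors outside genuine coupling are near-threshold
  values.
* The k-table is a maximum-likelihood construction, not a published
  tabulation; absolute threshold values depend on it beyond the k = 0
  identity, though simulated-responder recovery stays within one ladder
  step across the ladder interior.
* Per-channel significance maps are uncorrected by design; with 70 cells,
  ~3.5 false positives are expected per screen at α = 0.05.
* Cross-channel (two-signal) bicoherence, phase-amplitude coupling, and
  time-resolved coupling are out of scope.
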