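# Methods

This note documents the models, estimators, and design choices behind
`hmvoice`, including what the synthetic test bed does and does not
establish about real recordings.

## Harmonic model and MAP fitting

A voiced frame of N samples is modeled as a DC offset plus H harmonics of a
fundamental f0 with additive zero-mean Gaussian noise. For a fixed f0 the
model is linear in the 2H+1 coefficients, so the MAP estimate under a
zero-mean Gaussian coefficient prior is ridge-regularized least squares,
solved by orthogonal decomposition (never by explicitly inverting normal
equations, except in the vectorized candidate-scoring path where the
ridge-regularized system is well conditioned by construction).

Two numerical choices matter:

- **Gain handling.** Frames are normalized to unit standard deviation
  inside the fit and coefficients rescaled afterwards, with the fixed prior
  weight λ = 10⁻³·N on the normalized scale. This makes coefficients
  equivariant and the fit score exactly invariant under recording gain,
  which the feature contracts require (pitch, jitter, shimmer, HNR,
  spectral entropy and MFCC c1–c12 must not depend on microphone level).
- **Fit score.** The score used to compare pitch candidates is the profile
  Gaussian log-likelihood in which the noise variance is estimated from the
  *penalized* residual sum of squares (the prior shares the noise scale, so
  the quadratic penalty folds into the variance estimate), minus a Laplace
  model-order term (k/2)·log N with k = 2H+1. An earlier formulation that
  subtracted the raw prior penalty λ‖c‖²/(2σ̂²) from the log-likelihood is
  not scale-invariant — at high gain or high SNR it penalizes precisely the
  well-fitting candidates — and was rejected on that ground.

Model order is deterministic: H(f0) = floor(0.95·Nyquist/f0), capped at 10
for feature fits (HNR, voicing, refinement). HNR is
10·log10(E_harmonic/E_residual), capped at ±60 dB; a frame is voiced when
the HNR of its selected pitch candidate reaches 0 dB (configurable).

## Pitch tracking and octave-error suppression

Candidates live on a log-spaced grid (default 60–600 Hz, 24 bins/octave,
chosen for child and adolescent voices). Each non-silent frame is scored at
every candidate; scores are smoothed by a moving average over 5 adjacent
candidates; a first-order Markov prior — Gaussian in log2-pitch with σ = 0.1
octave per 10 ms frame — links successive frames, and the Viterbi algorithm
decodes the contour, breaking ties toward the lower candidate. The winning
candidate is then refined off-grid by a bounded scalar search of the raw MAP
score between its grid neighbors.

The octave problem has a specific structure here: a subharmonic candidate
f0/2 spans every partial the true candidate spans (the models are nested),
so no residual comparison can reject it. The discriminating signal is
complexity: during candidate scoring H is left *uncapped*, so the f0/2
candidate carries roughly twice the parameters, and the model-order term of
the score rejects it. With the cap applied during scoring (all candidates
below ~760 Hz would have H = 10 and identical complexity) the tie is
unbreakable — this is why scoring and feature fits use different H rules.
Candidate-score smoothing is retained as a stabilizer but does not by itself
suppress subharmonics: the score-peak width near a candidate is set by the
absolute frequency of the highest matched partial, which is the same for a
subharmonic, a fact verified empirically during development.

Measured on synthetic fixtures (0.5–2 s, HNR 10–20 dB, f0 100–400 Hz):
gross (octave-class) error 0% of frames, fine RMSE ≈ 0.2 Hz.

## Jitter, shimmer, and cycle marks

Jitter and shimmer use the standard "local" definitions: the mean absolute
consecutive difference of cycle periods (respectively amplitudes) over the
mean, in percent; below 3 cycles the value is missing and the frame is
excluded from the statistics.

Cycle marks — the per-cycle time and amplitude sequence the definitions
need — are extracted once per voiced run, not per 25 ms frame: the signal is
band-limited to its harmonic series (everything above (H+½)·f0 is noise
under the model and removed), resampled 16× for sub-sample timing, and one
mark is placed per waveform peak; per-cycle amplitudes are the least-squares
gain of each cycle against the mean cycle shape, which averages noise over
the full cycle rather than trusting one peak sample. Each frame then
summarizes the cycles its window covers, so the per-frame fields remain.

The within-frame alternative — peaks of the TV-HM reconstructed fundamental
— is implemented and kept (it is the right tool for smooth within-frame
modulation, and its envelope recovers amplitude ramps to within 5%), but it
systematically under-recovers *uncorrelated* cycle-to-cycle perturbation: a
B-term polynomial trajectory over the ~5 cycles of a 25 ms frame cannot
track cycle-rate modulation (recovery ≈ 0.3–0.8 of truth at B = 3), and
raising B makes the modulated carriers of adjacent harmonics nearly
collinear and the fit unstable without heavy ridge, which re-smooths the
very perturbation being measured. The segment-level marks recover realized
jitter within ±10–12% and shimmer within ±15% at HNR ≥ 25 dB.

Noise floors to keep in mind: peak-timing scatter adds ≈ 0.3–0.5 percentage
points of apparent jitter at 25 dB HNR and grows at lower HNR; amplitude
scatter adds ≈ 0.5–1 point of apparent shimmer at 25 dB. Perturbation
measures on heavily noisy voices are therefore upper bounds, which is the
expected behavior of local perturbation measures generally. The pipeline's
HNR estimate is itself biased low by a fraction of a dB when jitter/shimmer
are present (the fixed-f0 model misfits a perturbed frame slightly); HNR
recovery is validated at ±1 dB on perturbation-free fixtures.

## Frame analysis and standard measures

Segments are sliced into 25 ms frames at 100 frames/s; a frame is silent
when its RMS falls more than 40 dB (configurable) below the segment's
95th-percentile frame RMS — the percentile reference makes the rule immune
to isolated clicks and to global gain. Loudness is plain RMS. Cepstral
coefficients default to MFCCs: pre-emphasis 0.97, Hamming window, 26
triangular mel filters, log energies floored at 10⁻¹⁰, orthonormal DCT-II,
13 coefficients, with regression deltas (window 2, edges replicated)
applied once and twice; a linear-frequency cepstrum is available via
`cepstrum="linear"`. Spectral entropy is the Shannon entropy (nats) of the
log power spectrum shifted to non-negative (minimum mapped to zero) and
normalized to sum one; the min-shift resolves the sign ambiguity of log
power and keeps the quantity gain-invariant, and a degenerate flat spectrum
maps to the maximum ln K.

## Aggregation

Every frame measure is summarized by five statistics — mean, median, sample
variance (n−1; a singleton has variance 0), min, max — separately over
voiced frames (all measures) and unvoiced frames (loudness, cepstra,
entropy). A segment adds a seven-value duration block: voiced and unvoiced
run counts, total and mean run durations, and voiced-frame fraction. The
same five statistics compress a subject's segments into one vector per
conversational activity, and the four activity vectors (FMC, EC, SDAC, LC)
concatenate in fixed order into the subject vector (2185 dimensions per
activity, 8740 for all four). Missing blocks — a segment with no voiced
frames, a subject missing an activity — are NaN until analysis time, when
cross-subject median imputation fills them (logged per subject). Dimension
names are stable and parseable
(`activity.activity_stat.stratum.feature.segment_stat`), which is what the
prosodic/articulation feature-group selection keys on: prosodic = pitch,
jitter, shimmer, HNR, loudness; articulation = cepstra, spectral entropy;
the duration block is its own group.

## Evaluation protocol

Scaling is median/IQR (scikit-learn RobustScaler; zero-IQR columns pass
through), fitted on training rows only within every fold. The classifier is
an L1-regularized linear SVM (C = 1, no internal tuning). One protocol run
is: undersample the majority class to the minority size (28 in the
reference cohort); stratified five-fold CV; per fold compute AUC (rank
statistic, ties ½), sensitivity and specificity at the natural decision
threshold 0, and accuracy as their mean (balanced accuracy — appropriate
since folds are class-balanced by construction); average folds. One hundred
such iterations are averaged, and the 95% CI is the normal approximation
over iteration means (percentile CI available). Degenerate single-class
folds are resampled with a logged warning. The chance classifier draws
i.i.d. uniform scores on (−0.5, 0.5), independent of features and labels.

RFE drops the 10% of remaining features (at least one) with the smallest
absolute SVM weights per step, scores every visited subset with a
shorter-repetition version of the same balanced-CV AUC, and returns the
best-scoring subset, ties resolved toward fewer features. The partial
Spearman coefficient rank-transforms all three variables, residualizes the
x- and y-ranks on the covariate ranks, correlates the residuals, and uses a
t approximation with n−3 degrees of freedom for the p-value; a constant
covariate degenerates to the plain Spearman coefficient.

## Synthetic test bed: what it shows and what it does not

The voiced generator builds the signal cycle by cycle: each glottal cycle
draws a period T0·(1+e) and an amplitude 1+u with independent zero-mean
uniform perturbations, scaled (half-width 1.5·p% for a target of p%) so the
realized local jitter/shimmer match the target in expectation; the
*realized* per-cycle sequence is returned as ground truth and is what
recovery tests compare against. The cycle amplitude applies over the
pulse-centered phase interval, reflecting that one glottal pulse carries one
amplitude. Harmonic phases default to zero (pulse-like waveforms; phase is
not identifiable from any extracted measure), noise is white Gaussian with
variance set from the target HNR against the realized harmonic energy, and
f0 contours may be constant, piecewise-linear, or callable. The feature-
level cohort generator defaults to the reference cohort shape — 118
subjects, 90 cases vs 28 controls — with 1-SD group shifts (cases
lower-pitched, louder) and 4× case loudness variance among 20 exchangeable
noise dimensions: overlapping distributions, not a toy separation.

Passing tests on this bed establish that the estimators recover known
quasi-periodic structure under additive white noise and that the protocol
is leak-free, unbiased at chance, and deterministic under seeding. They do
not establish robustness to reverberation, channel coloring, overlapping
speakers, or non-pulse-like phase spectra — real conversational recordings
have all four — nor do they validate any clinical claim. Problem sizes in
the test suite (0.5–2 s fixtures, 20-iteration protocol runs where the
statistic allows it, 2-SD shifts for the feature-selection recovery test so
the planted pair is unambiguously informative) are the package's choices
for a fast, deterministic suite; the acceptance script runs the full
100-iteration protocol.

## Known limitations

- Segment annotations (who speaks when) are assumed given; no diarization.
- Cycle-mark extraction assumes one dominant waveform peak per cycle.
- The pitch grid (60–600 Hz) must bracket the speaker; octave suppression
  relies on harmonics being present above the fundamental.
- Median imputation of missing activity blocks ignores between-activity
  correlation.
- The accuracy definition (mean of sensitivity and specificity) and the
  iteration-level CI are stated conventions; other choices would shift
  headline numbers by fractions of a point.
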