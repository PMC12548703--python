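# Methods

`pamtonic` re-implements, as a tested pipeline with a ground-truth
simulator, an analysis of tonic posterior-auricular-muscle (PAM) surface
EMG during dichotic selective listening.  This note documents the models,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic studies can and cannot show about real recordings.

## The paradigm being modelled

A listener hears two competing streams, one per ear: 800 Hz tone bursts
(50 ms, 12 ms Hanning rise/fall) in one ear and brief rising chirps
(logarithmic sweep 100 Hz -> 9,800 Hz over 14.9 ms, unwindowed) in the
other.  Events are assigned to ears at random with onset-to-onset
inter-stimulus intervals uniform on 250-400 ms; each ear carries
occasional deviants, identical waveforms attenuated by 15 dB, recurring
every 3-20 events, which serve as detection targets in the attended ear.
A sequence of 600 events delivers on average 300 stimuli per ear and
lasts about 3.26 min.  Twenty listening trials per participant cross
attended side (left/right) with the tone-burst ear, five trials per
combination.  Surface EMG is recorded over both PAMs as unipolar
electrode pairs at 9,600 Hz with a trigger channel.

Two sequence-generator details are deliberately parameterized rather
than tuned.  A uniform integer gap on [3, 20] implies a deviant
probability near 8.7%, slightly below the nominally stated 9.4%; the gap
range is the exposed parameter and no tuning toward the probability is
attempted.  Event count per sequence is fixed at 600, the simplest
generator consistent with a 300-per-ear average; whether the original
study fixed count or duration is not derivable from the printed design.
The chirp is synthesized as an exponential-in-time frequency sweep of
exactly 14.9 ms; cochlear-delay-derived chirp constructions are out of
scope because only the duration and the frequency endpoints matter to
the analysis (the reflex time-zero is the chirp offset).

## Synthetic EMG model

Each PAM is a latent band-limited (20-500 Hz, 4th-order Butterworth)
Gaussian source with instantaneous standard deviation

    sigma(t) = background_rms * (1 + a * 1[attended == PAM side]) * exp(-t / tau)

- `a` (`attention_gain`, default 0.3) is the multiplicative ipsilateral
  tonic boost.  The downstream z-scoring is affine-invariant, so
  additive versus multiplicative action is not identified by the
  analysis; multiplicative keeps amplitudes positive.
- `tau` (`decay_tau_s`, default 150 s) is an exponential decay standing
  in for the observed monotone decline of tonic activity over a trial;
  no functional form is identified by the analysis, and exponential is
  the simplest positive monotone choice.

Each stimulus adds a biphasic difference-of-Gaussians reflex template
whose positive peak sits `reflex_peak_ms` (default 15 ms, within the
stereotypical 5-30 ms range) after the stimulus time-zero, scaled by a
unit-mean lognormal per-trial factor (`reflex_trial_cv`, default 0.3),
an ipsilateral/contralateral drive pair (1.0 / 0.6; laterality of the
reflex drive is a free generator choice), and the deviant attenuation
factor.  The default chirp reflex amplitude is 1.5 x the background RMS:
the single-trial PAM reflex is of the order of ongoing EMG and becomes a
clean waveform only through averaging, which is exactly why averaged
reflexes work as reliability anchors.  This scale also matters
numerically: zero-phase filtering (comb pre-ring, long FIR kernel tails)
smears a small fraction of reflex energy into pre-stimulus windows in
proportion to reflex amplitude, and with an unrealistically large
single-trial reflex that leak would contaminate the pre-stimulus tonic
measurement that the time-locked analysis relies on.  The tone-burst
reflex default is 0.05 (essentially absent): a 12 ms rise time fails to
elicit the short-latency reflex, which is what makes tone-locked
responses fail the reliability screen while chirps pass.

Electrode mixing: each source is split onto its two unipolar channels
with opposite half-amplitude polarity, plus shared common-mode noise
(RMS 0.3) and 50 Hz line contamination with harmonics (amplitudes 1/k,
default fundamental amplitude 0.5).  Line noise is mostly common-mode
with a +-20% differential fraction so that a realistic residual survives
the bipolar derivation and the comb filter has real work to do.
Artifact bursts (Poisson, default 0.02/s, 50-200 ms, 10-30 x background,
Hanning-tapered) hit single electrodes.  Simulation is single-precision
at the native 9,600 Hz so the resampling stage is genuinely exercised;
EMG dynamics leave ample headroom to float32 resolution.  All randomness
derives from a hierarchical seed stream (master -> participant ->
trial -> noise/common/line/reflex/artifact), so recordings are
byte-stable in the master seed, and scaling reflex amplitudes leaves
the noise realization untouched (which is what makes paired
reflex-independence simulations exact).

Between-participant variation (the default sampler): background RMS and
reflex amplitudes lognormal with CV 0.4, attention gain and decay
constant with CV 0.2.  Real inter-individual PAM variability is known
only qualitatively; these are order-of-magnitude choices.

What the generator does *not* emulate: motor-unit spike trains and their
rectified-EMG statistics (the source is Gaussian), electrode geometry
and impedance drift, eye/jaw artifacts with characteristic spectra, and
attention effects on the reflex itself (deliberately absent, since the
analysis treats reflex modulation as out of scope).  Passing tests
therefore show that the *pipeline* recovers the effects it assumes, not
that real PAM data behave this way.

## Preprocessing

Bipolar derivation (channel 1 minus channel 2 per PAM), polyphase
resampling to 4,800 Hz behind a Kaiser anti-alias FIR (~80 dB stopband;
the alias-rejection contract is >= 60 dB above the target Nyquist), a
comb notch at 50 Hz and every harmonic up to Nyquist (Q = 35), and a
20-1,000 Hz linear-phase FIR band-pass of order 4,800 (Hamming design),
both filters applied forward and backward for zero net phase.

Numerical choices: the comb's lag-96 recursion is evaluated as 96
decoupled first-order chains (numerically identical to the dense
difference equation, orders of magnitude faster); the forward-backward
band-pass is applied as a single FFT convolution with the self-convolved
kernel (exactly the two-pass operator for a symmetric FIR); edges are
handled by odd-reflection padding (3 x kernel length for the FIR, 20
periods for the comb) so start-up transients stay inside regions that
later trimming discards.  The filter order is interpreted at the
4,800 Hz rate, i.e. a 1 s impulse response, matching the stated
post-resampling application order.

## Epoching, screening, normalization

Epochs span [-1000, +1000) ms around each stimulus time-zero (chirp
offset; tone-burst rise end), linearly detrended over the full epoch and
baseline-corrected by the mean over [-250, 0) ms.  Windows are half-open
(baseline [-250, 0), post [0, 250)); the reflex window [5, 30] ms is
closed.  At 4,800 Hz an epoch is 9,600 samples.

Epoch SNR is `10*log10(var[0,250) / var[-250,0))`; epochs are retained
iff their SNR lies within 3 SD of the mean over all epochs of the
2 x 2 x 2 design (computed once, outliers included), separately for
standards and deviants.  The per-cell quota is the smallest retained
count across cells *and* participants (a study-level pass); the quota
epochs with SNR closest to the mean SNR are selected per cell, ties
broken by presentation order.  The reference mean for selection is
recomputed over retained epochs (the alternative - reusing the
pre-rejection mean - differs negligibly and is not separately exposed).
Amplitudes are normalized per PAM and participant by the maximum
absolute amplitude over [5, 30] ms across the eight cell-average
waveforms (4 standard + 4 deviant), which preserves every within-PAM
relative difference.

Reliability: per cell, standards are split into odd/even presentation
halves, each half averaged, and the Pearson r of the two averages over
[5, 30] ms computed; a participant passes with r >= 0.4 in at least 6 of
8 cells (which forces >= 2 of 4 per PAM).  A zero-variance average
yields the -inf fail sentinel, distinct from a genuine r = -1.

## Tonic analyses

Ongoing (primary): 1 s centered moving-RMS envelope of each preprocessed
signal (edge windows truncate; the first 5 s are discarded anyway); a
region of interest starting 5 s after the first stimulus onset and
lasting 180 s, split into five 36 s segments and summarized by means.
Per PAM and participant, all 100 values (20 trials x 5 segments) are
pooled; values strictly outside the [2.5th, 97.5th] percentile band
(linear-interpolation percentiles; boundary values retained) are
removed; the rest are z-scored (sample SD) and categorized by PAM side,
stimulus type at that side, attended side, and segment, averaging the
five contributing trials per cell.

Time-locked (secondary): a 10 ms moving-RMS envelope, epoched [-100,
+100) ms at chirp offsets, restricted to exactly the trials whose
non-rectified epochs were selected.  Per PAM, chirp sides are collapsed
and the 2 x 2 (attended x standard/deviant) cell averages are jointly
z-normalized by the mean and SD of their concatenated pre-stimulus
samples; no subtractive baseline is applied.  Because the minimum ISI is
250 ms and the centered 10 ms window smears at most 5 ms, no reflex
energy (earliest 5 ms post time-zero) can reach [-100, 0) ms.  The
toward/away contrast pools each PAM's same-side/opposite-side averages
per participant; normalization is per PAM first (forced by the stated
per-PAM 2 x 2 normalization), pooling after.

## Statistics

Fully within-subject 2 x 2 x 2 repeated-measures ANOVA on the
first/last-segment reduction, separately for the sides of tone-burst and
chirp delivery, with factors PAM location, listening condition
(toward/away), and time (first/last).  Every effect is tested against
its own effect-by-subject interaction with df (1, N-1); sphericity is
moot at two levels, and each F equals the squared paired t of the
corresponding subject-level contrast (asserted in the tests).  Effect
sizes are partial eta-squared.  Pre-stimulus contrasts use two-tailed
paired t-tests.  Alpha is 0.05, uncorrected, rejection at strict
p < alpha.  An all-zero difference vector returns t = 0, p = 1;
zero-variance nonzero differences are an error.

One known generative mismatch: because the attention gain is
multiplicative and the tonic level decays, the simulator produces a
listening-condition x time interaction that the human data did not show;
the recovery criteria therefore check the two main effects and the
absence of a spurious PAM-location effect, not the interaction pattern.

## Problem sizes used in the test suite

The acceptance-style simulations run at reduced scale, chosen once:
sequence statistics over 1,000 seeded 600-event sequences; 20 replicate
recovery studies with N = 17, 20 trials of 185 events (~60 s) and the
region of interest scaled proportionally (start 1.5 s, 55 s, five 11 s
segments); paired reflex-independence studies with N = 8 and 150-event
trials; reliability-gate studies with 20 + 8 participants and 100-event
trials; type-I calibration on 2,000 table-level simulations.  Ongoing-
only runs skip epoching entirely, and the reliability/time-locked runs
skip the envelope analysis, so each criterion pays only for what it
measures.

## Known limitations

- The Gaussian source lacks the spiky amplitude distribution of real
  EMG; SNR-based rejection rates on real data will differ.
- The reflex template is a stylized difference of Gaussians, not a
  measured PAM reflex waveform.
- Attention effects on the reflex, long-latency event-related
  components, and EEG co-recordings are out of scope.
- EDF import/export is not provided; recordings use a documented
  .npz + JSON sidecar container (WAV for rendered stimuli).
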