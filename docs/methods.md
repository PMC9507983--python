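# Methods

## Stimulus model

The exposure language is four trisyllabic words over 12 unique syllables
(three interchangeable versions, A/B/C). A stream presents each word exactly
`reps_per_word` times (default 100, i.e. 400 words / six minutes at the
300 ms syllable rate) in pseudorandom order with no immediate repeats.
Generation samples each successor uniformly from the words with remaining
quota, excluding the predecessor and weighting by remaining quota; dead ends
trigger a bounded full resample (`GenerationError` after 1000 attempts —
never observed for 4-word lexicons). Onsets are stimulus-nominal: the stream
starts at t = 0 and syllable onsets lie on an exact `syllable_duration`
grid, deliberately not sample-aligned.

Transitional probabilities are estimated from bigram counts over the
syllable sequence. The within- and between-word means average over
transition *instances* (token-weighted). Within words the successor is
deterministic, so the within mean is exactly 1.0; at boundaries the
empirical mean fluctuates around 1/3 with binomial noise.

Foils: partwords splice a word edge across a boundary (X₃Y₁Y₂ or Y₂Y₃X₁),
keeping exactly one within-word syllable pair; nonwords chain position-2,
position-1, position-3 syllables of three distinct words, which by the
lexicon's positional-uniqueness property guarantees that no adjacent pair
ever occurs in a stream. Both properties are re-verified by scan at
construction time.

## Synthetic EEG

`simulate_recording` emulates the statistical structure the analysis
assumes, not biophysics. Per 12-word epoch n it adds

    word_amp · cos(2π t / 0.9 + φ_w,n) + syllable_amp · cos(2π t / 0.3 + φ_s,n)

with φ_w,n ~ von Mises(0, κ_word(n)) and φ_s,n ~ von Mises(0, κ_syllable),
t measured from the epoch onset. Phase jitter is applied per analysis epoch
rather than per word — a deliberate simplification that makes the expected
ITC analytically tractable: the resultant of the injected phases has
expectation R(κ) = I₁(κ)/I₀(κ), returned in `GroundTruth`. κ_word
interpolates linearly from `kappa_word_start` (default 0.5) to
`kappa_word_end` (default 4.0) across epochs, injecting a positive word-rate
learning trajectory; κ_syllable is constant (default 8, R ≈ 0.94). κ = 0
gives uniform phase; κ = ∞ disables jitter entirely (ITC → 1 exactly in the
noise-free case).

Background noise is Gaussian, spectrally shaped to 1/f^α (α default 1) by
rFFT scaling and RMS-normalised per channel (`noise_sigma` default 5 µV
against 1–2 µV signal components — comfortable desk-scale SNR, not matched
to human recordings, for which no effect-size anchor exists). Topography is
schematic: ROI channels carry the signal at gain 1, other scalp channels at
0.3, and the two mastoids (M1/M2) carry noise only. The default 32-channel
montage uses standard 10–20 labels with an 18-electrode frontocentral ROI;
any other channel count gets generic labels with the first half as ROI, and
the ROI is always config-overridable. A 1.5 s noise-only tail leaves room
for onset jittering.

Behavioural simulation is driven by one latent learning strength L ∈ [0, 1]:
2AFC success probability 0.5 + 0.4 L; rating category means separate
linearly (word 2.5 + 1.2 L, partword 2.5 + 0.3 L, nonword 2.5 − 0.6 L,
discretised to the 1–4 scale with SD 0.8 response noise) — values chosen
once to put the L = 0.5 composite rating score near the ~0.8 range typical
of adult learners while keeping L = 0 at zero; detection RTs are
520 − 120·L·(position−1) ms plus 60 ms Gaussian noise, with misses at 12 %
and uniform stray presses at 0.1 per target.

## Entrainment analysis

Epochs are fixed-length: round(12 × word_duration × fs) samples (5530 at
512 Hz), starting at every 12th word onset mapped to the nearest sample
(max timing error < 1 ms). Because the stimulus grid is not sample-aligned,
adjacent epochs may share at most one boundary sample; they never share
words. Epochs running past either end of the recording (possible after
surrogate jittering) are dropped and logged.

ITC uses raw, untapered FFT phases (the statistic is phase-only; tapering
would only alter bin leakage), giving a bin grid of fs/5530 ≈ 0.0926 Hz for
the canonical epoch. The word (1/0.9 s) and syllable (1/0.3 s) rates fall
exactly on bins 12 and 36, i.e. 1.111 and 3.333 Hz — the conventional
"1.1/3.3 Hz" labels are rounded. Target bins are selected nearest-neighbour
with ties to the lower frequency, and the selected frequency is logged.
Amplitude is discarded (unit phasors); an amplitude-weighted variant is
deliberately not offered as a default. ITC requires ≥ 2 retained epochs.
Under uniform phase E[ITC] = √π/(2√N); this closed form anchors the null
calibration tests.

The surrogate draws one independent integer uniformly from the 1801 values
in [−900, 900] ms per word onset, re-sorts, and reruns epoching, artifact
screening and ITC with identical parameters. A single surrogate per
participant is the default; zero jitter reproduces the actual ITC
bit-for-bit (a regression-tested identity). Actual-vs-surrogate comparison
is a paired t-test with Cohen's d = mean difference / SD of differences; a
zero-variance difference vector is flagged (`degenerate_variance`) instead
of reporting an infinite statistic.

Artifact screening replaces manual inspection and ICA with a peak-to-peak
threshold (default 150 µV over the ROI channels); this is a documented
substitution — ocular-artifact decomposition is out of scope. Filtering
(band-pass 0.1–20 Hz, 60 Hz notch) is zero-phase FIR via mne, since the
downstream statistic is phase-based.

## Time course and mixed models

Bundles are sliding windows of 5 epoch positions with step 1
(B = n_epochs − 5 + 1; 33 epochs → 29 bundles; each spans 54 s). A bundle
with fewer than 2 retained epochs yields NaN, never a fabricated value.
Bundle numbers missing from more than 50 % of participants are excluded.
With the default 400-word stream the arithmetic gives 29 bundles; the
module follows the arithmetic rule and leaves any dataset-specific epoch
bookkeeping to the retained-mask machinery.

Learning models are linear mixed-effects fits (statsmodels `MixedLM`,
REML): `response ~ bundle` with a participant random intercept, bundle as a
1-based numeric covariate, optional `group` and `bundle:group` (or age)
fixed effects, complete-case on the response, no random slopes by default.
Fixed effects are reported as Wald z with normal-approximation p-values and
an F-equivalent z²; the method string is embedded in every `LMMResult`.
Satterthwaite-type denominator degrees of freedom are not computed —
at the design sizes used here (hundreds of observations) the normal
approximation is close, and simulation shows the reported SEs are, if
anything, slightly conservative for tabular data. A caveat that is
structural rather than numerical: adjacent bundles share 4 of their 5
epochs, so within-participant trajectories are strongly autocorrelated and
a random-intercept model understates slope uncertainty for EEG-derived
series (stationary-signal simulations show 95 % CIs covering zero slope
only ~50–80 % of the time). Slope *estimates* remain unbiased; tests that
need calibrated error rates in this package therefore aggregate across
participants or across independent simulations. Singular random-intercept
fits are flagged, not silenced.

The surrogate time-course comparison stacks actual and surrogate bundle
series with a datatype indicator and fits
`response ~ bundle * datatype` (+ participant intercept); the
`bundle:datatype` interaction isolates stimulus-locked growth from drift.

## Behavioural scoring

Rating composite = mean word rating − mean pooled foil rating (with the
balanced 4 + 4 foil design this equals the mean of the two foil-category
means). Single-key responders are flagged by zero rating variance. 2AFC
accuracy is tested against 50 % with a one-sample t and Cohen's d.

Detection: a press at time t hits an unconsumed target with onset o when
0 < t − o ≤ window (1200 ms adult, 1400 ms child — four syllable
durations); a press at exactly 0 ms is a false alarm. Presses are processed
in time order, each taking the nearest preceding eligible target, and each
target consumes at most one press; unassigned presses are false alarms.
(The alternative first-target rule differs only when windows overlap; the
nearest-target choice is recorded here as the package's convention.)
hit_rate = hits / targets, normalised_fa = false alarms / targets, mean RT
per target syllable position, RT priming = (S1 − S3)/S1 — invariant to
baseline RT scaling by construction. Positions without hits yield NaN, and
priming is undefined (NaN) if S1 is missing.

Group statistics use pingouin (repeated-measures/mixed ANOVA with partial
η²; Greenhouse–Geisser output retained alongside uncorrected df) plus a
one-df linear contrast across ordered levels computed from per-participant
contrast scores.

## Problem sizes and determinism

Everything randomised funnels through `numpy.random.default_rng` seeds
recorded in outputs; the full pipeline is byte-reproducible from one seed.
Validation simulations use reduced montages (4 channels, 2-channel ROI)
because the statistical claims under test concern epoch counts and
participant numbers, not channel counts; the parameter-recovery benchmark
runs 20 group simulations of 24 participants × bundles 1–26 at the full
400-word stream length. The acceptance script's quantities are exact design
statistics and use the canonical 400-word stream.

## Known limitations

- Per-epoch (not per-word) phase jitter means the generator cannot emulate
  within-epoch phase drift; real learning presumably accumulates word by
  word.
- The synthetic topography is a two-level gain map; no volume conduction,
  no age-dependent anatomy, no ocular artifacts beyond amplitude outliers.
  Passing recovery tests therefore demonstrate correctness of the analysis
  chain, not robustness to real-world EEG artifact structure.
- EDF files are read (via mne) but not written; the native interchange
  container is npz + events TSV.
- The LMM inference caveat for overlapping bundles above applies equally to
  any analysis of sliding-window series with this model family.
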