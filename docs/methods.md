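# Methods

`voicemark` implements a speech-and-language biomarker analysis for
separating bipolar disorder (BP) from major depressive disorder (MDD) in
euthymic patients: acoustic pause/amplitude features from ~60 s monologue
recordings, linguistic and negation-aware sentiment features from their
transcripts, FDR-corrected group comparison, and a multi-classifier
evaluation harness. Because the clinical recordings such a design relies on
are private, the package ships a first-class synthetic cohort generator
with known ground truth; every downstream stage is specified, implemented
and tested against that truth. This note records the models, the parameter
choices that matter, and what the synthetic results do and do not show.

## The synthetic cohort generator

The generator emulates a two-group study (41 BP, 150 MDD by default), each
subject contributing a WAV recording, a transcript and ten demographic
fields.

**Audio.** A waveform is an alternation of voiced segments and true
silences. Voiced segments are harmonic bursts — a fundamental drawn
uniformly from 120–220 Hz plus two overtones at amplitude ratios
0.6/0.3/0.1, normalised so the segment's peak equals the per-segment
amplitude drawn from the group's `voiced_amplitude` distribution, with 5 ms
raised-cosine edge fades. No phonetic realism is attempted: every acoustic
feature the pipeline extracts depends only on the signal envelope. Silences
sit at a −80 dBFS uniform-noise floor, ~45 dB below the default detection
threshold, so detector behaviour on synthetic input is unambiguous.

Pause structure is driven by two distributions: `pause_fraction` (fraction
of total duration that is silence) and `pause_length_ms` (individual
silence lengths, default uniform 250–450 ms). The pause budget is
`round(fraction × duration)` quantised to the 5 ms envelope hop grid, and
every segment boundary sits on that grid. Two consequences, both
deliberate:

* a framed RMS envelope detector measures each inserted silence *exactly*
  (no edge smearing), so detector-vs-oracle equivalence tests are sharp;
* the realised pause fraction matches a point-mass `pause_fraction` to
  better than one part in 10⁴ at 60 s / 16 kHz (the residual is grid
  rounding), which is what the point-mass recovery tests assert.

The last drawn silence is truncated to meet the budget exactly and may
therefore fall below the 200 ms detection gate; recovery tolerances allow
for one such sub-gate remainder per subject.

**Transcripts.** Tokens are whitespace-delimited pseudo-words written
`surface/tag`. Each token draws, independently, (i) a lexical class —
polarity class, one of eight emotions, stop word, person pronoun, topic
keyword, or plain filler — with surfaces drawn from the bundled synthetic
lexica, and (ii) a raw POS tag from `pos_tag_probs`. Negation words are
inserted before content tokens with probability `negation_prob` and carry
the unmapped tag `neg`, so they are counted by dictionary membership (as
the Negations feature) and never inflate a tag-based POS count. Chinese
segmentation is not emulated; the tagger interface is pluggable and the
bundled slash tagger recovers the generated tags exactly, which is what
lets POS/stop-word/annotation truth be asserted with equality rather than
tolerance.

**Calibration.** Group centres follow the direction of the clinical
summary tables: BP pauses less (fraction centred 0.19 vs 0.30), speaks
more (words centred 201 vs 146), at lower and less variable amplitude
(0.16 ± 0.05 vs 0.40 ± 0.17 full scale); demographics are sampled from the
published group proportions; lexical mixes centre near the published
annotation/emotion frequencies. Spreads, the voiced-segment length law
(uniform 0.8–2.2 s) and the keyword inventory are the package's own
calibration choices. A handful of topic keywords ("spirit", "energy",
"emotion", "normal", …) carry group-dependent probabilities so the
classifier harness has a linguistic signal in addition to the acoustic
one. Demographics never feed the audio/text process — group differences
there are only the configured marginal ones.

**What this does not show.** Synthetic cohorts establish that the
*pipeline* is correct (features recover known truth; tests are calibrated;
the harness detects injected separation and nothing under label
permutation). They say nothing about effect sizes, classifier accuracy or
feature importance in real clinical speech; the published headline
performance numbers are properties of a private dataset and are not
reproduced here.

## Acoustic features

The envelope is short-window RMS: 10 ms windows, 5 ms hop — the 200 ms
minimum pause then spans ≥ 39 windows, comfortably resolved. A frame is
silent when its RMS is ≥ 35 dB below the recording's *maximum* short-window
RMS; the threshold is interpreted relative to programme level because
consumer editors define silence that way, and it is configurable. Maximal
silent runs of ≥ 200 ms become pauses; each pause is credited at most
500 ms (emulating silence deletion with a maximum deletion length —
subtraction of the shortened from the original length then gives cumulative
pause). Exclusion of >500 ms silences, rather than capping, is a
configuration switch. Degenerate inputs: a waveform shorter than one
analysis window yields no pauses; non-finite samples are an input error;
an all-silent recording has no reference level and yields no pauses.

Two ratios follow: cumulative pause over total speaking time (the
*original* recording duration — the subtraction construction makes the
original length the natural denominator) and cumulative pause per word.
Amplitude statistics are max, min, max-absolute sample value, and "average
peak" = RMS × 1.414, the sinusoidal crest factor (√2 to three decimals);
the constant is validated against a pure sine in the tests. Peak and
maximum-peak are near-duplicates but both are emitted, matching the
published variable list. Amplitudes are computed on the noise-reduced,
pause-intact signal.

Noise reduction is a spectral gate (STFT, 256-sample frames) whose per-bin
noise profile is the mean magnitude of the lowest-energy `profile_s`
seconds of frames; bins below 2× the profile are attenuated to 0.02. It
defaults to **off**: synthetic input is clean, and the stage exists for
recordings with a real noise floor. `profile_s = 0` is the identity.

## Linguistic features

Thirteen POS-derived frequencies (adjectives, conjunctions, adverbs,
nouns, verbs, measure words, prepositions, pronouns, time words, negations,
first/second/third-person pronouns), each a count divided by total word
count. Tag-mapped categories count via a configurable raw-tag → category
table; negations and person pronouns count by dictionary membership, not
tag. Numerals and particles are available behind an extended flag but are
not part of the canonical 13. Tokens with unmapped tags count toward word
count only.

Stop words are counted against a one-word-per-line stop list and then
removed before TF-IDF. TF-IDF uses TF = raw count / document length and
smoothed IDF = ln((1+N)/(1+df)) + 1 (the unsmoothed ln(N/df) is a switch;
exact corpus-duplication invariance is a property of the unsmoothed
variant). The keyword vocabulary is the top-k terms by corpus-summed
TF-IDF mass, ties broken lexicographically — a deterministic selection
rule; k defaults to 75 and is configurable within 50–500. Each subject
then gets the 75-dimensional keyword vector plus its sum ("top word sum")
and the sum divided by total word count. Speaking rate is words per second
of original (pause-intact) duration.

## Sentiment features

Per-word polarity follows `Score(w) = Negation × Orientation(w)`:
orientation is the signed lexicon score (0 when absent), and Negation is
−1 when a negation-dictionary word appears in the scope window before the
target (default scope: exactly one token; configurable). Repeated
negations inside one window flip once. The aggregate score is the mean
per-word score over all tokens — mean rather than sum because the observed
clinical magnitudes (~0.03) are word-count-independent — and is bounded by
the largest |orientation| ≤ 1.

Annotation frequencies count polarity-lexicon hits per class (Positive,
Neutral, Negative, Non-opinionated, Not-a-word) over total word count;
Not-a-word tokens stay in the denominator. Emotion frequencies count
emotion-lexicon hits per emotion (eight NRC-style classes) with the same
negation weighting: a negated hit contributes −1 to the signed count,
which is floored at 0 before normalising; an absolute-count mode is the
switch. The bundled lexica are small synthetic stand-ins in the external
resources' file formats (licences prevent bundling the real dictionaries);
loaders accept user-supplied files in the same formats.

## Group comparison

Welch's two-sided t-test for continuous variables (chosen over the pooled
test because the default groups are 41 vs 150), Pearson chi-squared
without continuity correction for integer-coded categorical demographics.
Degenerate cases are pinned: both groups constant and equal → p = 1;
constant and different → p = 0; a single observed level in a categorical
variable → p = 1. All compared variables (everything except the individual
TF-IDF keywords, mirroring the published table layout) form one pooled
Benjamini-Hochberg family by default — the comparisons span several
feature sets and a single family controls the FDR across all of them — with
a per-family mode behind a flag. Summaries report mean, median and IQR so
either published presentation style can be read off.

## Classification harness

118 default feature columns: 10 demographic + 13 POS + 75 TF-IDF + 14
sentiment + 6 acoustic. The five remaining text metrics (word count,
speaking rate, stop-word count, the two top-word-sum metrics) sit behind
an `extended_features` flag; 13 + 75 + 14 = 102 is the only textual
decomposition consistent with the declared counts, so the canonical layout
excludes them. Demographics are single integer-coded columns (binary 0/1;
education and hospitalization ordinal by level order; small unordered sets
as level codes) — one-hot expansion would break the 10-column demographic
block, so the column count wins over encoding orthodoxy; the provenance
map records every column's family.

Protocol: stratified 4:1 train/test split (8 BP subjects land in the
default test partition); SMOTE — synthetic minority rows interpolated
between a minority sample and one of its k = 5 nearest minority neighbours
— balances classes on training data only, applied inside each
cross-validation fold by default (leakage-safe; once-globally is a flag,
and k auto-reduces with a warning when the minority is small); train
metrics are the arithmetic mean over 10 stratified CV folds evaluated on
untouched fold-validation parts; test metrics come from a final model fit
on the balanced full training set. Eight classifier families run at
library defaults (logistic regression's iteration cap is raised so the
default solver converges on unscaled features); because defaults drift
across library versions, every hyperparameter actually used is written to
a lockfile alongside each report. BP is the positive class — the
published degenerate SVM row (sensitivity 1.000, specificity 0.000,
precision ≈ test-set BP prevalence) identifies it — and AUC is the primary
metric, computed from predicted probabilities where available and the
decision function otherwise. Permutation importance is the mean test-AUC
drop over repeated single-feature permutations, ranked descending with
ties broken by feature name.

## Problem sizes and numerical choices

The test suite runs its unit layer on scaled-down cohorts (typically 6–30
subjects, 15–20 s recordings, 100–400 words) and reserves the full
default cohort (191 subjects × ~60 s) for the structural and harness
checks; calibration checks use 10,000 null replicates for the type-I-error
bands and 2,000 all-null families for FDR control, sizes at which the
Monte-Carlo error is small against the asserted bands. Chance-level
calibration of the harness shuffles labels over 50 seeds. The
reproduction script regenerates the default cohort from its seed at run
time; WAVs are written as 16-bit PCM, and generation is byte-reproducible
for a fixed (configuration, seed) pair.

## Known limitations

* Harmonic-burst audio has none of the spectral variability of speech;
  pause and amplitude features transfer, pitch-type features would not
  (none are used).
* The identity between generated tags and extracted POS counts is by
  construction; with a real tagger the POS features inherit the tagger's
  error characteristics.
* The synthetic lexica are tiny; real ANTUSD/NRC resources change the
  scale of sentiment features, though not the scoring rules.
* The published clinical effect sizes and classifier performance are not
  reproducible from synthetic data and are not claimed.
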