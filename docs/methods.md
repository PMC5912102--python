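# Methods

`gazetraits` implements a pipeline that predicts coarse personality-trait
ranges (low / medium / high) from head-mounted eye-tracking recordings made
during an everyday errand, together with a synthetic-cohort generator that
makes every stage testable without human data.

## Data model and preprocessing

A recording is a single gaze stream sampled nominally at 60 Hz. Coordinates
are normalised to the tracking range: the calibrated field maps to the unit
square with the origin at the top-left corner and y growing downward, which
makes the heatmap's top-left-first cell enumeration natural. Pupil diameter
is in millimetres and absent (NaN) when the tracker lost the pupil.
Binocular hardware is assumed to have been reduced to one cyclopean stream
upstream.

A sample is **erroneous** when the pupil is absent or gaze falls beyond 150%
of the tracking range on either axis. We read the 150% rule per axis as the
interval of length 1.5 centred on the range, i.e. [−0.25, 1.25]; a radial
reading is also defensible, but the per-axis interval is symmetric and easy
to test. Participants are excluded when more than 50% of samples are
erroneous, or when gaze is constant (longest identical-value plateau on
either axis) for more than 30% of valid samples — the constancy cutoff is a
design choice sitting safely below a pathological case near 40% and far
above plausible genuine behaviour.

## Event detection

* **Fixations** — dispersion-threshold (I-DT) grouping. The dispersion of a
  candidate group is `(max x − min x) + (max y − min y)` over its valid
  samples (the classic formulation); the threshold is 2.5% of the tracking
  range (0.025) and the minimum duration 100 ms. The grouping is greedy:
  from each onset the minimal 100 ms group is tested; on success it grows
  sample-by-sample until the threshold would be exceeded; on failure the
  onset advances by one sample. Groups with more than 50% erroneous samples
  are discarded. A brute-force re-statement of this contract (recomputing
  the dispersion from scratch at every step) lives in the test suite and
  must agree exactly on random traces, which pins down the greediness
  convention.
* **Saccades** — every inter-fixation gap is a candidate, accepted when it
  lasts ≤ 500 ms and its peak velocity (first differences between
  consecutive valid samples, divided by their actual time gap) reaches
  ≥ 200% of the tracking range per second; candidates with more than 50%
  erroneous interior samples are discarded. Amplitude is the distance
  between the bounding fixation centroids; direction is `atan2` of the
  centroid displacement with y inverted so "up" is positive. Fixations up
  to 500 ms may contain smooth pursuit; no separate pursuit class exists.
* **Blinks** — the tracker vendor normally labels blinks; here they are
  inferred as maximal pupil-absent runs of physiological duration
  (75–500 ms). Shorter runs are noise, longer ones track loss.

## Windows and features

The recording is cut into sliding windows with 50% overlap (half-open
`[start, start + size)`, trailing partial window dropped). Windows with more
than 50% erroneous samples, fewer than 2 valid samples, or no fixation and
no saccade are discarded. An event belongs to the window containing its
midpoint; a window's context label (way-to-shop / shop / way-back) is the
one covering the majority of its span, ties to the earlier context.

Each retained window yields a fixed 207-dimensional vector in four blocks.
The total and the four families are the pipeline's contract; the exact
per-family inventory is this package's canonical convention:

* **raw gaze (34)** — min, max, mean, SD (population), median, range, IQR
  and skewness for each of x, y, sample speed and sample acceleration over
  valid samples, plus the valid-sample fraction and the x–y Pearson
  correlation. Degenerate statistics (constant signals, empty difference
  series) are 0.
* **heatmap (64)** — an 8×8 histogram of the window's valid gaze points
  inside the per-window 2.5th–97.5th percentile interval on each axis
  (outlying extrapolated points are thereby ignored), cells enumerated
  row-major from the top-left, counts normalised to sum 1. Windows with no
  surviving point fall back to the uniform 1/64; a zero-width interval puts
  all mass in row/column 0.
* **events (53)** — fixation count/rate, duration and dispersion summaries,
  time-in-fixation, within-fixation speed; saccade count/rate, duration /
  amplitude / peak-velocity summaries, a normalised 8-bin direction
  histogram, the large-to-small amplitude-class ratio (capped at 10) and
  time-in-saccade; blink count/rate and duration summaries; pupil summaries
  over valid samples plus mean/SD of per-fixation pupil means and
  variances. Statistics of empty event sets are 0.
* **n-grams (56)** — events are encoded as symbols: 16 saccade symbols
  (8 directions × large/small, large meaning amplitude ≥ 0.1 range) and, in
  the second encoding, 2 fixation symbols (short/long at 0.3 s). For each
  encoding (saccade-only and interleaved) and each n ∈ {1..4}, the n-gram
  histogram of the window's symbol sequence yields: distinct count, max,
  min, mean and variance of the non-zero entries, and the lexicographic
  indices of the most and least frequent n-gram (ties to the smallest
  index; −1 indices when the sequence is shorter than n). The amplitude and
  duration class thresholds and the lexicographic-index encoding of the
  categorical "most frequent n-gram" are package conventions.

## Labels, classifier, nested cross-validation

Trait scores (NEO-FFI neuroticism, extraversion, openness, agreeableness,
conscientiousness; Perceptual Curiosity; CEI-II) are binned per trait at the
empirical 1/3 and 2/3 percentiles (linear-interpolation quantiles), computed
once on the full cohort; scores at or below the lower boundary are "low",
above the upper boundary "high". Identical scores always share a bin, so
bins are only approximately thirds in the presence of ties.

The window-level classifier is a standard scaler (fitted on training rows
only; zero-variance features centred but not scaled) followed by a random
forest with 100 trees, maximum depth 5, and up to 15 features considered per
split. Windows inherit their participant's range; a participant's prediction
is the majority vote over their windows, ties broken by summed class
probability, then by the lower range.

Nested cross-validation cuts the cohort into contiguous blocks of five
participants: each fold takes one block as test, the following five
participants as validation, and the rest as training. Every candidate — a
(window size, feature subset) pair from {5, 10, 15, 30, 45, 60} s × {all
207, each family alone, all minus each family} — is trained on the training
block and scored by participant-level macro F1 on validation; the winner
(ties to the larger window, then the larger subset) is retrained on
train ∪ validation (scaler refitted on the merged set) and applied to the
test block. Test predictions concatenated over folds cover every participant
exactly once.

The whole scheme is repeated with different seeds. A repetition seed
re-randomises **both** the forest initialisation and the participant order
from which the cyclic blocks are cut, so the repetition mean averages over
fold composition as well as forest randomness; with a frozen assignment the
repetitions would repeatedly measure one arbitrary configuration, which on
null data is a wide-variance draw (the per-configuration spread of
chance-level F1 at n = 42 is roughly ±0.1).

## Evaluation

Performance is macro F1 over the three ranges (per-range F1 is the harmonic
mean of precision and recall, with 0/0 → 0 — needed for constant
predictors, which score exactly 1/6 on balanced truth). Three baselines are
run the same number of times: a uniform-random range per participant, the
modal training range predicted for all test participants, and a label
permutation of the full nested CV (participant→range assignment shuffled,
multiset preserved). Means carry 95% percentile-bootstrap confidence
intervals over the repetition scores (1,000 resamples).

Reliability compares majority-vote predictions reconstructed from window
subsets — first vs second half of each recording by window midpoint, way I
vs way II, and shop vs both ways — pairing repetition i with repetition i,
correlating the ordinally encoded (0/1/2) predictions over common
participants, and averaging through Fisher's z (degenerate pairs skipped and
counted). Feature–trait correlations average each feature per participant
over 15 s windows, then correlate with raw trait scores.

## Synthetic cohorts

The generator emulates the everyday-errand setting: 12.51 min recordings at
60 Hz, ~19.6% track loss, way/shop/way contexts at 40/20/40% of the
duration, and approximately Gaussian trait scores on questionnaire-like
scales. Recordings alternate fixations (log-normal durations, mean 0.28 s,
SD 0.12 s; Gaussian positional jitter with SD 0.0015 range units, chosen so
that sustained fixations stay inside the 0.025 dispersion threshold) and
saccades (log-normal amplitudes, mean 0.11 range; von Mises directions; a
minimum-jerk position profile whose duration, 20 ms + 100 ms per unit
amplitude, keeps peak velocities above the 2 range/s acceptance threshold).
Blinks arrive as a Poisson process (12/min, ~150 ms) and additional
pupil-absent runs (log-normal, ~1.5 s) are inserted until the target loss
fraction is met; during lost tracking the reported gaze freezes at its last
position, as trackers typically do. Pupil diameter is a base value plus an
AR(1) drift (φ = 0.995) and white measurement noise. The generator emits
its own event plan as ground truth, so detector recall is measurable; recall
is computed over recoverable truth fixations (≥150 ms, ≤50% erroneous),
since fixations swallowed by track loss are discarded by the pipeline's own
rule rather than missed.

Trait→behaviour coupling is configurable: an effect specification gives each
trait a slope, in units of the parameter's nominal between-participant SD,
on any generator parameter; an independent noise term adds trait-free
individual variation. A zero specification leaves recordings statistically
independent of traits. The "strong" preset shifts fixation duration, saccade
amplitude and blink rate by one SD per SD of one trait.

What the generator does **not** model: smooth pursuit, head and body
motion, scene content, questionnaire measurement error, or any genuine
trait–gaze physiology. Passing tests therefore show that the pipeline
recovers programmed statistical structure of oculomotor parameters at
realistic sampling, loss and cohort sizes — not that personality is
predictable from real gaze data.

## Problem sizes in tests and drivers

End-to-end tests use 42-participant cohorts with 4-minute recordings and a
reduced candidate grid (15 s and 30 s windows with all features) over 20
repetitions; the analysis drivers use 12–30 participants and 5 repetitions.
These sizes give dozens of retained windows per participant — enough for
stable majority votes — while keeping a full run on one core to minutes.
Statistical expectations (chance at 1/3, constant predictor at 1/6,
recovery of one-SD-per-SD effects well above 0.55) do not depend on the
full 12.5-minute duration.

## Known limitations

* The per-family feature inventory beyond the documented 34/64/53/56 split
  is a convention; other decompositions consistent with the same total are
  possible.
* The I-DT greediness convention (minimal-window test, grow, emit, resume
  after) is one of several; the oracle-equivalence test pins this one.
* Tertile bins are cohort-level, so test-fold label frequencies are not
  independent of training folds; this mirrors the analysed protocol and is
  shared by all baselines.
* With heavy ties in trait scores, bins can be strongly unbalanced; the
  binning refuses only the fully degenerate all-equal case.
* The label-permutation baseline permutes participant-level assignments
  once per repetition; window labels follow their participant.
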