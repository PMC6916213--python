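# Methods

## The model

Every sample is one patient-day: all of that patient's notes from one
calendar day, concatenated in note-type order (pulmonary, radiology,
cardiology), lowercased, split on non-alphanumeric runs, mapped to integer
ids against a frequency-ranked vocabulary (id 0 = padding, id 1 =
out-of-vocabulary, frequency ties broken lexicographically), truncated to
the first `T` tokens and post-padded with zeros. The supervision signal is
the *death window*: with initial window length `B` days and `P` classes, a
document written `d` days before death belongs to class
`min(floor(d / B), P − 1)`. Class 0 is the `B`-day window adjacent to
death; the last class absorbs everything older than `(P − 1)·B` days. The
published description of the window encoding stops at "one-hot encodings of
a given regular time interval"; the capped-floor mapping is this package's
choice, made so that the softmax head's output is a well-defined date range
before death.

The network is embedding → LSTM → flatten → dense. The LSTM is the
standard gated recurrence (input, forget, output and input-modulation
gates; see the `progression_model` docstring for the equations); the
flatten layer unrolls the `(T, L)` hidden matrix so the dense head sees the
entire hidden trajectory, not only the final state. For `P > 1` the head
is a softmax trained with categorical cross-entropy; `P = 1` switches to a
sigmoid with binary cross-entropy (a mortality score).

Training is plain mini-batch gradient descent — no momentum, no adaptive
rates — with analytic backpropagation through time, implemented in NumPy in
float64. Choices that matter:

* **Initialization**: embeddings uniform in ±0.05, all weight matrices
  uniform in ±0.08, biases zero except the forget-gate bias, which starts
  at 1 so the memory cell retains information early in training. All draws
  come from one seeded generator; runs are bit-reproducible.
* **Learning rate**: default 0.01; the synthetic experiments in this
  repository use 0.2 with batch size 32, which converges within 25 epochs
  at their scale.
* **Gradient clipping**: global-norm clip at 5.0, a standard guard against
  the occasional exploding backprop-through-time gradient. The gradient
  correctness test bypasses the clip.
* **Ties** in the predicted class break toward the smaller class id (the
  window closer to death).

Correctness of the arithmetic is established two independent ways: the
vectorized recurrence is compared against a scalar-loop implementation of
the same equations (agreement to 1e-10), and the analytic gradients are
compared against central finite differences on a tiny model (agreement to
1e-5 on every parameter).

## Boundary head and segmentation

The timeline of `N` consecutive `B`-day initial windows (window 0 adjacent
to death) is segmented by a binary signal: 1 at window `j` opens a new
segment; runs of windows merge into irregular time-lapse segments.
Signals and segmentations with a leading 1 are in bijection, and the
segments always partition the `N·B`-day horizon. Segmentation is
cohort-level: all patients' samples at the same days-before-death offset
are pooled into the same window.

The boundary decision is made by a dedicated sigmoid head with weights of
shape `(T·L, 1)`, kept separate from the classification head. Its input
for window `j` is the **difference between the mean flattened LSTM outputs
of windows `j` and `j − 1`**, not the window's own content. The reason is
identifiability: "window `j` starts a new segment" is a statement about
change relative to the previous window, and two windows inside the same
homogeneous phase of disease have, in expectation, identical content — a
head reading only the window's own features cannot separate the first
window of a phase from the later ones. The difference-of-means input makes
the boundary a linear function of exactly the quantity that defines it.

The head is trained self-supervised, with no access to any planted truth:
window `j` gets target 1 when the total-variation distance between the mean
predicted class distributions of windows `j` and `j − 1` is at least 0.3
(a fixed default: half the maximum possible shift between two adjacent
windows' distributions), and logistic regression on the difference features
is fitted by gradient descent. At inference the head's output is
thresholded at 0.5; window 0 is always 1 so that segments partition the
timeline; empty windows never open a segment and are skipped when forming
differences. Segmentation quality is evaluated against the generator's
planted stage boundaries, since the published description of the 0/1
sequence is not operational enough to define an internal metric.

## Evaluation protocol

The 70:30 train/test split is at the *patient* level — every sample of a
patient lands on one side — to prevent leakage between a patient's own
notes. The LSTM is scored by exact window-class agreement. The baselines
(scikit-learn `LinearRegression` and `LinearSVR` over bag-of-words counts
of the shared vocabulary) predict a continuous days-before-death value and
are scored by the within-window rule `|predicted − actual| ≤ B`, boundary
inclusive. The two metrics are not directly comparable — the baselines'
rule is more lenient for adjacent near-misses — but both are reported per
window size, and the qualitative ordering (coarser windows are easier) is
what the tests assert.

On a 180-day history (`B = 30`, `P = 6`), a 360-day window would place
every sample in a single class, which the trainer rejects as degenerate;
the coarse end of the window sweep is therefore `B = 90`, `P = 2`.

## The synthetic corpus

The generator emulates the structural features of an end-of-life note
corpus that the pipeline is supposed to exploit, with defaults chosen once:

* 3 latent stages with boundaries 120/60/0 days before death over a
  180-day history (`P·B` with the default `B = 30`, `P = 6`), each stage
  owning a disjoint theme vocabulary (curated clinical terms for the
  early / progressing / terminal stages), on top of a shared background
  vocabulary;
* sentences of 10–14 words, of which `round(0.4 × length)` are stage theme
  words — high enough for LDA to find themes, far from the 100 % that would
  make the task trivial;
* note days drawn per patient per day as a Poisson event with rate 0.06
  (≈ 11 note-days per patient over 180 days), multiplied by 2.0 inside the
  final stage, emulating the densification of visits near death; 1–3 notes
  per note day across the three note types; every patient is guaranteed at
  least one note;
* all deaths at a fixed calendar origin, since every analysis is relative
  to the death date.

What it does **not** emulate: real clinical language (negation, section
headers, abbreviations, misspellings), gradual rather than abrupt stage
transitions, per-patient variation in stage timing, correlations between
note types, and censoring. Passing tests therefore demonstrate that the
machinery recovers planted temporal-theme structure, not that it would
reach any particular accuracy on real notes — the published accuracies on
the confidential clinical corpus are explicitly not reproduction targets.

## Atlas construction

LDA is fitted *per segment* on sentence-level bags of words (sentences
split on `.!?` + whitespace), because the atlas presents each segment's
themes independently; default 3–5 topics and 10 theme words per topic.
Theme-word ranking ties break lexicographically for determinism. A
sentence's score is distinct theme-word hits (repeats count once) divided
by its own token count — per-sentence rather than corpus-average length
normalization, the sharper of the two readings — and the 30 % threshold is
inclusive, consistent with 3 hits in a 10-word sentence qualifying.
Sentences are attributed to the topic with the most hits (lower topic id on
ties), ranked by fraction, then hits, then first occurrence, deduplicated
on exact text, and clamped to `k`. A segment with no sentences is kept
empty with a warning; one with fewer sentences than topics is themed with
as many topics as it has sentences.

The spiral rendering is an Archimedean spiral with one revolution = 360
days and death at the centre; it is written as plain SVG text with fixed
two-decimal coordinate formatting, so identical inputs give byte-identical
files.

## Problem sizes

The self-contained experiments run at desk scale, chosen to exercise every
stage in seconds to minutes on one CPU: 200 patients (≈ 2 700 samples) with
`T = 100`, `v = 16`, `L = 16` for the learning experiments, 25 epochs at
the 30-day window; 80-patient corpora for the ten-seed boundary-recovery
experiment; `V` capped at 500 (the synthetic vocabulary is smaller). The
documented full-scale defaults (`V = 10 000`, `v = 64`, `T = 1000`) remain
the package defaults for real corpora.

## Known limitations

* The LSTM reads at most the first `T` tokens of a merged day document;
  there is no content-based filtering of non-COPD material.
* The boundary head detects change between *adjacent* windows only; a
  gradual drift spread over many windows may never trip the threshold.
* Cohort-level segmentation assumes patients share a common staging
  clock relative to death; per-patient segmentation is out of scope.
* `LinearSVR`/`LinearRegression` baselines extrapolate freely; their
  within-window accuracy depends on the label range and is not bounded
  away from the LSTM's metric in any formal sense.
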