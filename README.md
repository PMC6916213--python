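# copdatlas

Chronic obstructive pulmonary disease (COPD) progresses over years, but the
evidence of each stage is buried in free-text clinical notes that arrive
irregularly — sparsely while a patient is stable, densely near death.
`copdatlas` is a research tool for characterizing that progression on a
days-before-death axis from a longitudinal corpus of pulmonary, radiology
and cardiology notes plus a death-date table. It is aimed at clinical-NLP
and health-services researchers who want an interpretable timeline of
end-of-life disease dynamics rather than a black-box risk score.

It implements a two-step pipeline:

1. **Irregular time-lapse segmentation.** Each patient-day's notes are
   merged into one document, integer-encoded against a frequency-ranked
   vocabulary of size *V*, and padded to *T* tokens. A four-layer model —
   embedding (*V* → *v*), an LSTM with *L* hidden units, a flatten layer,
   and a dense softmax head — is trained by mini-batch gradient descent to
   predict the *death window*: the class `min(⌊d/B⌋, P−1)` where *d* is the
   document's days before death and *B* is the initial window length (30,
   90 or 360 days). The LSTM follows the standard gate equations

   ```
   i_t = σ(W_hi h_{t−1} + W_xi x_t + b_i)      f_t = σ(W_hf h_{t−1} + W_xf x_t + b_f)
   o_t = σ(W_ho h_{t−1} + W_xo x_t + b_o)      g_t = tanh(W_hg h_{t−1} + W_xg x_t + b_g)
   c_t = f_t ⊙ c_{t−1} + i_t ⊙ g_t             h_t = o_t ⊙ tanh(c_t)
   ```

   with the per-batch dimensional chain (T) → (T, v) → (T, L) → (T·L) → (P).
   A dedicated sigmoid head over the flattened LSTM output then emits a 0/1
   boundary signal over the *N* consecutive initial windows; consecutive
   windows up to the next 1 merge into *irregular time-lapse segments*.
   Setting P = 1 turns the dense head into a sigmoid mortality score.

2. **The COPD atlas.** For the *n* (= 7) most recent segments before death,
   a latent Dirichlet allocation model is fitted per segment; the top words
   of each topic are its *theme words*, and a sentence is *representative*
   when ≥ 30 % of its tokens are theme words of its best topic (≈ 3–4 theme
   words in a 10–14-word sentence). The top *k* (= 10) sentences per
   segment are rendered as JSON, Markdown, and a spiral timeline SVG where
   the equal-window baseline (green) is compared with the irregular
   segments (red).

Real end-of-life note corpora are confidential, so the package ships a
first-class synthetic-corpus generator that plants the structure the
pipeline must recover: latent pre-death stages with disjoint theme
vocabularies, 10–14-word sentences with a configurable theme-word fraction,
and note density that increases in the final stage.

Accuracy comparisons against bag-of-words linear-regression and
support-vector baselines (patient-level 70:30 split; a baseline prediction
counts as correct when it lands within *B* days of the true death date) are
built in.

## Worked example

```
copdatlas all --out demo --seed 7
```

generates a 120-patient synthetic corpus (3 planted stages with boundaries
120/60/0 days before death over a 180-day history), trains the model at
B = 30 days with P = 6 classes, evaluates, segments, and builds the atlas:

```
3262 notes, 120 patients -> demo/corpus
lstm    B=30    49.69%
lr      B=30    73.79%
svm     B=30    73.79%
3 segments from 7 initial windows
atlas with 3 segments -> demo/atlas
```

The LSTM's 49.69 % is held-out window-classification accuracy — against a
16.7 % chance level for six classes, and close to the ceiling imposed by the
generator (content identifies the stage, and each 60-day stage spans two
30-day windows). The LR/SVM rows use the more lenient within-±30-days rule
on a continuous prediction. The boundary signal `[1,0,1,0,1,0,0]` merges
the seven initial windows into exactly the three planted stages, and
`demo/atlas/atlas.md` shows the recovered themes — the segment adjacent to
death is dominated by terminal-care vocabulary (hospice, bipap, morphine,
tachycardia), the 120–60-day segment by exacerbation-and-therapy vocabulary
(oxygen, steroid, nebulizer):

```
## 60-0 days before death
- topic 0: pulmonale, cor, sedation, cyanosis, intubation, tachycardia, bipap, hospice, ...
1. follow range review bipap intubation stable hospice morphine ... (7/15 theme words)
```

`demo/atlas/atlas.svg` is the spiral timeline: one revolution = 360 days,
death at the centre, green arcs for the equal 30-day windows, red arcs with
day-range labels for the irregular segments.

The same stages are available as library calls (`synthetic_corpus`,
`preprocess`, `progression_model`, `segmentation`, `evaluation`, `atlas`);
see the module docstrings.

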