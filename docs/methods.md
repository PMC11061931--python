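# Methods

## The model

The package treats drug repurposing detection as a two-stage problem:
an unsupervised *representation* stage that turns a chronological
abstract corpus into per-drug vector time series, and a supervised
*prediction* stage that classifies fixed-length windows of those series.

### Temporal embeddings

A single skip-gram-negative-sampling (SGNS) model is trained
incrementally.  Documents are consumed strictly in date order; the
documents falling between consecutive snapshot dates form a chunk, the
model trains `epochs_per_chunk` passes over each chunk only, and the
input vectors are deep-copied into a snapshot after every chunk.
Because one model persists across the whole pass, all snapshots share a
coordinate system and a word's vectors are directly comparable across
time — the usual Procrustes alignment needed when training separate
per-period models is unnecessary by construction.

Conventions chosen where the underlying method leaves freedom:

* **Vocabulary** is re-scanned and extended at each chunk; earlier
  vectors are retained and trained further.  New words get small uniform
  input vectors and zero output vectors (the word2vec convention).
* **Frequency threshold** applies to *cumulative* corpus frequency: a
  word enters snapshots once its total count reaches `min_frequency`
  and never drops out, so snapshot vocabularies grow monotonically.
* **Learning rate** decays linearly from `alpha` (0.025) to `min_alpha`
  within each chunk and restarts at the next chunk.  No decay of the
  influence of earlier chunks is applied beyond what continued SGD does
  naturally.
* **Determinism**: fixed context window (no random window shrinking),
  single-threaded numba kernel with sequential per-pair updates, all
  sampling from one seeded generator — identical inputs give bitwise
  identical snapshots.

Defaults (context window 5, minimum frequency 50, 5 epochs per chunk,
dimension 50, bi-monthly snapshots) are the literature-scale settings;
desk-scale experiments lower `min_frequency` to match their corpus size.

The schedule convention: snapshots at `start + k·interval` months for
k = 1, 2, …; the start date itself is not a snapshot.  Calendar
arithmetic clamps to month ends (a month-end date plus n months is the
target month's end), and day-of-month overflows such as "November 31"
are read as the month's last day.  Under this convention the bi-monthly
schedule for a corpus spanning 1965-11-30 to 2021-11-30 has exactly
336 snapshots.

### Inceptive drift

For diagnostics, `drift_series` reports the cosine similarity of a
word's vector at every snapshot against a fixed reference snapshot; the
value at the reference is 1 by definition and declines as the word's
context changes.  `nearest_neighbours` ranks co-vocabulary words by
cosine at one snapshot (ties broken lexicographically).

### Labels

Two labelers produce dated (drug, condition) events:

* **Stream labeler** — triples filtered to TREATS/PREVENTS (AFFECTS is
  parsed but excluded by default), names normalized, stream sorted by
  date.  A drug's earliest-dated condition(s) are its baseline; each
  later first-seen pair is an event at its publication date.  Treating
  the debut as baseline rather than an event is a deliberate choice:
  repurposing presupposes an existing use, and without it every drug's
  first mention would be a positive.
* **Release labeler** — the first release is baseline; a pair present in
  a later release but in no earlier one, for a drug already listed,
  is an event at that release date.  Events published before the first
  release are invisible in principle (they are part of the baseline), so
  evaluations anchor the release grid before the first event publication.

Name normalization lowercases, strips tokens that are pure numbers or
dosage units (ml, mg, g, mcg, ug, µg, l, iu, %, mg/ml) and collapses
whitespace; it is idempotent and rejects names that are all dosage.
Disease-synonym merging is intentionally **not** attempted; distinct
condition strings count as distinct conditions.

Events map to the earliest snapshot dated on/after the event (round
up), so a window ending at the mapped snapshot ends at or before the
publication it predicts.  Two events mapping to the same snapshot
produce a single positive label (labels are per-snapshot binary).

### Windows, balancing, splits

An instance is `window_length` consecutive snapshot vectors for one drug
(present at every position — gaps disqualify a window), labelled by the
final snapshot only.  Negatives are all full-coverage windows whose
final label is 0; this is the natural complement of the positive
definition.  Balancing keeps every positive and down-samples negatives
uniformly (seeded) to equality.  An optional intra-window subsampling
step (`subsample_step`) takes every m-th snapshot inside the window, and
`truncate_windows` shortens instances to their trailing vectors so a
grid can explore history lengths without rebuilding datasets; semi-annual
release labelling uses `SnapshotSchedule.subsample` the same way.

`stratified_kfold` gives each fold a stratified 1/k test portion and a
stratified `validation_fraction` share of the remaining training portion
(defaults: 5 folds → 20% test; 10% validation of the training portion).
Balancing is applied to windowed instances, before splitting.  Because
overlapping windows of one drug can straddle folds, a grouped mode keeps
all of a drug's windows in one fold; it is off by default to mirror
class-only stratification, and it weakens the exact ±1 class-ratio
guarantee.

### Classifier

Architectures are declarative layer stacks over {LSTM, BiLSTM, GRU,
SimpleRNN, Conv1D, MaxPool, Dropout}; the head is always a single
sigmoid unit and the recurrent layer feeding it returns only its final
state.  Pooling is max-pooling and must follow a convolution; the Conv1D
kernel width defaults to 3 (filter counts and pool sizes are the
explored quantities).  Layers are implemented in numpy with exact
backpropagation(-through-time), verified against finite differences in
the test suite, and follow the common framework conventions — GRU with
separate input/recurrent biases (3·(d·u + u² + 2u) parameters), LSTM
with a unit forget-gate bias (4·(d·u + u² + u)), Glorot input kernels,
per-gate orthogonal recurrent kernels.

Training: binary cross-entropy on logits, Adam at its default step size
(10⁻³), at most 100 epochs, early stopping on validation loss with
patience 10 and restoration of the best-validation weights, threshold
0.5 at prediction time.  All stochastic stages (initialisation,
shuffling, dropout, down-sampling, folds) derive from a run-level seed;
per-fold classifier seeds are offset by the fold index so folds are
independent yet reproducible, and folds are fixed per run-level seed so
grid points are comparable.

## The synthetic world

Each condition owns a topic of 20 characteristic words; each drug
treats one baseline condition; every abstract is a bag of tokens around
exactly one drug mention, with 70% of context tokens drawn from the
drug's topic mixture and 30% from a background vocabulary.  A drug with
a repurposing event mixes the new condition's topic in with a weight
ramping linearly from 0 to `drift_magnitude` over the `drift_lead`
intervals ending at the event date; the TREATS triple is published
`publication_lag_months` later, and cumulative release tables pick it up
at the next release boundary.  Drift therefore *precedes* the recorded
evidence, which is what makes prediction from embedding windows solvable
in principle — and with `drift_magnitude = 0` the task is unsolvable by
construction, giving a clean negative control.

What the generator deliberately does not model: realistic biomedical
language, sentence structure, MeSH indexing, citation structure,
negative or retracted relations, disease synonymy, multi-condition
drugs, or secular vocabulary growth.  Passing tests on this world show
that the pipeline recovers a planted context-shift signal under its own
assumptions; they say nothing about effect sizes in real literature.

## The benchmark

The canonical benchmark (`drugdrift.experiments`) uses 1,800 drugs, 25
conditions, event rate 0.65, 24 bi-monthly intervals over 2000–2004,
two documents per drug per interval (3,600 per interval), drift lead 18
intervals, publication lag 2 months, and windows of 20 snapshots — sizes
chosen so that the balanced dataset comfortably exceeds 2,000 instances
while the complete pipeline (two drift conditions plus cross-validation)
runs in minutes on one CPU.  Embeddings use the default dimension 50,
window 5 and 5 epochs per chunk with `min_frequency = 2` (each drug has
exactly two mentions per interval, so every drug is present from the
first snapshot).  The classifier is the strongest stream-label stack:
Conv1D 32 → MaxPool 2 → Dropout 0.2 → BiLSTM 32 → Dropout 0.2, batch 64.

Note an intentional hardness of the task: for an event drug, windows
ending shortly before the event contain most of the drift ramp but are
labelled 0; the classifier must distinguish *completed* drift from
drift in progress, not merely detect drift.  Accuracies well below the
drift magnitude are therefore expected.

## Numerical and degenerate-input choices

* Cosine similarity is computed in float64 and clipped to [−1, 1];
  zero vectors are an error.  The drift value at the reference index is
  set to exactly 1.
* Snapshot files store float32 vectors with 9 significant digits, which
  round-trips float32 exactly.
* Empty chunks copy the previous snapshot bitwise; an empty lexicon
  restriction warns rather than fails; `tokens_per_doc = 0`, unsorted
  corpora/streams, duplicate release dates, all-dosage names, zero-class
  balancing and classes smaller than k are errors.
* Nearest-neighbour and event orderings break ties lexicographically so
  outputs are stable across runs.

## Known limitations

* The SGNS trainer keeps all pair arrays for a chunk in memory; it is
  sized for desk-scale corpora, not the full literature.
* With very sparse drug mentions, early snapshots are noisy and a drug's
  window coverage can start late; the benchmark sidesteps this by
  guaranteeing uniform mention counts.
* Multiple events per drug are supported by the labelers but the
  synthetic generator plants at most one per drug.
* The grouped (leakage-free) fold mode trades away the exact class
  balance guarantee; the default mirrors plain class stratification.
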