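# Methods

## Language models over reads

**Word n-gram model.**  Each read is one sentence.  It is tiled from
position 0 into non-overlapping words of `word_length` bases (default 7);
the trailing fragment shorter than a word is dropped, and any window
containing a non-ACGT character is dropped while later windows keep their
positions.  Word length 7 keeps the closed vocabulary at 4^7 = 16,384 — small
enough that every word can be enumerated, large enough that word frequencies
are discriminative; model quality is not very sensitive inside 5–7, and 8 is
the practical memory ceiling for the count tables.  The model stores exact
counts of (history, next word) pairs for every history length 0..n
(default n = 3, a trigram history) — counting all suffixes up front makes
backoff a dictionary lookup.  Sentences are not padded: words near the read
start condition on truncated histories.

Probabilities use additive smoothing over the closed vocabulary,

    P(w | h) = (count(h, w) + alpha) / (count(h) + alpha * 4^L),

with `h` the longest suffix of the query history that occurred in training
(the empty history always qualifies), and alpha = 0.01 by default.  A closed
DNA vocabulary removes any unknown-word handling, and an untrained model
collapses exactly to the uniform distribution.  Corpus perplexity is the
geometric-mean inverse word probability, `exp(-mean log P)`; a uniform
independent model over w words scores exactly w.  All internal arithmetic is
in natural logs; the ARPA persistence format converts to log10 as that
format requires.  The ARPA files carry the smoothing metadata in comment
lines and each history's smoothed unseen-word mass in the backoff field, so
the importer can invert the smoothing formula and recover the integer
counts exactly — round-trip perplexity is bit-stable, and entry counts are
validated against the `\data\` header on import.

**Character RNN.**  A plain tanh recurrent network (per layer
`s_t = tanh(U x_t + W s_{t-1} + b)`) with a 4-way softmax output over
A, C, G, T; an LSTM adds cost without a meaningful perplexity gain at these
corpus sizes.  The production default is 2 layers of 300 units, mini-batch
200, learning rate 2e-3; the test suite uses 1 layer of 16–32 units.
Training is truncated backpropagation through time (window 50 characters)
with Adam and global gradient-norm clipping at 5.0.  Weights initialize
uniform(-0.08, 0.08) from the configured seed; data shuffling and the
90/10 train/validation split use the same seed, so training is
bit-reproducible.  The hidden state resets at read boundaries (reads are
independent molecules), reads containing N are excluded from training, and
scoring skips positions at or after the first N in a read.  The best
weights by validation cross-entropy are kept, so the returned model never
regresses across epochs.  Perplexity is `exp(mean cross-entropy)` over
next-character predictions; one forward pass per position yields the full
4-way distribution.

## Built-in corrector and external tools

The built-in corrector exists so the tuning loop can be exercised
hermetically; it is a deliberately simple instance of the k-spectrum
paradigm whose quality varies realistically with k.  k-mers counted at or
above `solid_threshold` (default 2) in the dataset being corrected are
solid; at every read position covered exclusively by insolid k-mers the
three alternative bases are scored by how many covering k-mers they would
make solid, and the best is applied only if it strictly improves on zero.
At most `max_corrections_per_read` (default 4) substitutions are made, left
to right; read length and order are always preserved (substitution-only —
Illumina errors are overwhelmingly substitutions), and no reverse-complement
canonicalization is applied anywhere (the simulator emits forward-strand
reads).  The fixed threshold is deterministic and adequate at the ≥30X
coverages the sampler guarantees; it is exposed as a flag.  k-mers are
packed 2 bits/base into 64-bit codes (k ≤ 31), solidity of whole read sets
is resolved with one sorted-array search, and only positions with no solid
cover are revisited in a short per-read loop.

External correctors are declared as a command template with `{input}`,
`{output}` and `{value}` placeholders plus a parameter grid.  Tools tuned by
a genome-length-style parameter get an explicit (e.g. multiplicative) value
list, since an arithmetic ±δ step is meaningless across 1M–120M; the hill
climb then walks list indices.

## The tuner

The language model is trained once on the complete uncorrected dataset.
Correction runs on a subsample sized by the Lander–Waterman identity
C = N·L/G to the coverage target (default 30X; below ~30X solid and insolid
count distributions blur and spectrum correctors stop correcting), drawn
uniformly without replacement with original order preserved; datasets under
the target, or with unknown genome length, are used whole.  The objective
`f(k) = perplexity(LM, correct(sample, k))` is evaluated for the current
value and its ±δ neighbors (δ = 1 grid step by default; out-of-range
neighbors count as +inf), the walk moves to a strictly lower neighbor with
ties toward the smaller value, and stops when the current value is at least
as good as both neighbors — non-strict, so plateaus terminate — or at the
iteration cap.  All starts (default: the single grid midpoint) share one
memo table, so distinct corrector invocations never exceed the grid size,
and the global minimum over everything evaluated is returned before the
full dataset is corrected at that value.  A corrector failure at some value
is recorded, excluded from the walk, and never retried.

N-gram perplexity is computed on the whole corrected sample.  RNN scoring
uses a uniform subsample (min of 50,000 reads and 1% of the sample) because
RNN evaluation is much slower per character; the same read indices are used
at every parameter value, so comparisons across k are paired rather than
independently noisy.

## Synthetic data

`generate_genome` emits an i.i.d. uniform ACGT string; `simulate_reads`
draws `ceil(C·G/L)` forward-strand reads with uniform starts (with
replacement) and i.i.d. substitution noise, keeping per-read truth.  The
standard validation fixture is a 100 kb genome at 50X with 100 bp reads and
a 2% per-base substitution rate — desk-scale, but deep enough that solid
k-mers dominate, as the method assumes.

Error injection supports three models.  A deletion event removes
`deletion_length` contiguous bases at a uniform valid index; an insertion
event inserts `insertion_length` uniform bases; a substitution event
replaces `substitution_count` distinct uniform positions with bases drawn
uniformly over all four (so 1 in 4 substitutions is silent, and the
expected Hamming distance of a 4-position event is 3).  Rate classes set
the error mass per read: `low` draws the number of single-base events
uniformly from {1..5}, `high` from {6..10} — single-base events make the
class equal to the number of error bases, and make perplexity damage scale
with the class for every error type, including deletions (a single
contiguous deletion of any length damages a roughly constant number of
words under tiled segmentation, which would decouple the class from the
signal).  `fixed` applies exactly `fixed_count` events of the configured
magnitudes, which is how the L−d / L+I length contracts are exercised and
how segment-style (contiguous) injections are expressed.  In the `mixture`
model the type is drawn equiprobably per event.  Substitution positions are
drawn without replacement within an event ("k positions" reads as a set).

What the simulator does not emulate: coverage biases, quality-score
structure, strand sampling (a reverse-complement option exists but is off
by default, matching the corrector's no-canonicalization convention),
platform-specific indel profiles, and repeats (the genome is i.i.d.
uniform).  Passing tests therefore show that the perplexity signal tracks
correction quality under idealized uniform-coverage substitution noise, not
that it is robust to real library artifacts.

## Evaluation

With simulated truth available, correction quality is measured directly:
base accuracy (fraction of bases matching truth after correction — the
stand-in for a reference-based alignment rate, and stated as such) and EC
gain `(removed − introduced) / errors_before`, the standard net-benefit
definition in the error-correction literature; a no-op corrector scores 0
and a perfect one 1.  `errors_before = 0` yields gain 0 by convention.
Correlations use the plain product-moment coefficient
(`scipy.stats.pearsonr`).

## Numerical and procedural choices

* Grid ties in the hill climb and in final selection break toward the
  smaller parameter value (cheaper downstream).
* Termination uses ≤ rather than < against neighbors, guaranteeing
  termination on flat profiles.
* Seeds: every stochastic step (genome, reads, subsampling, RNN training,
  injection) takes an explicit seed; the fixture derives child seeds from
  one master seed via `numpy.random.SeedSequence`.
* Problem sizes in the test suite: the fixture sweep runs 12 k values over
  a 30,000-read sample per seed, with five seeds for the direction and
  ranking checks; RNN checks use 1-layer desk-scale models on a few
  thousand reads.  These sizes were chosen so the full suite exercises the
  complete pipeline end-to-end in well under an hour on one core.

## Known limitations

* The perplexity objective is evaluated under a model trained on the full
  uncorrected dataset, so each scored read's own noisy n-grams are part of
  the training counts.  With additive smoothing this gives a singleton
  noisy context roughly a 100-fold advantage (at alpha = 0.01) over an
  unseen corrected continuation, which systematically disfavors corrections
  made adjacent to other errors.  On the synthetic fixture this shifts the
  perplexity argmin about two grid steps above the accuracy optimum — the
  anti-correlation across the grid remains very strong (|r| ≈ 0.98), but
  the final ranks of near-tied k values (the top of the fixture's accuracy
  profile spans ~1e-4 in absolute accuracy) are not reliably resolved.
  Discount-style smoothing or leave-one-read-out scoring shrink but do not
  remove this bias; both are out of scope here.
* The built-in corrector is substitution-only and greedy; it is a test
  substrate, not a competitor to production correctors.
* Paired-end mates are treated as independent reads; no strand handling.
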