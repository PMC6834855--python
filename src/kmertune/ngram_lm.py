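"""Word-based N-gram language model over segmented reads.

Each read is cut into non-overlapping words of ``word_length`` bases (the
segmentation length, 7 by default) and treated as one sentence.  The model
estimates

    P(W_i | W_{i-1}, ..., W_{i-n})

by exact counting with additive (add-alpha) smoothing over the closed
vocabulary of all ``4**word_length`` ACGT words, using the longest suffix of
the query history that was seen during training.  The corpus perplexity is
the geometric-mean inverse word probability

    PP = exp( -(1/m) * sum_i log P(W_i | history_i) )

i.e. the inverse probability of the test set normalized by the number of
words m.  Lower perplexity means the corpus is better predicted by the model;
a uniform independent model over w words has perplexity exactly w.

Models persist in the standard ARPA n-gram text format (log10 probabilities);
natural-log arithmetic is used internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .readset_io import ReadSet

__all__ = [
    "NGramError",
    "NGramModel",
    "UniformWordModel",
    "segment_read",
    "train_ngram",
    "corpus_perplexity",
    "export_arpa",
    "import_arpa",
]

_BASES = frozenset("ACGT")


class NGramError(ValueError):
    """Invalid model parameters, vocabulary violations or empty corpora."""


def segment_read(sequence: str, word_length: int) -> list[str]:
    """Tile `sequence` into non-overlapping words of `word_length` bases.

    Windows start at position 0; a trailing fragment shorter than
    `word_length` is discarded, and any window containing a non-ACGT
    character is dropped (subsequent windows keep their positions).
    """
    if word_length < 1:
        raise NGramError("word_length must be >= 1")
    words = []
    for start in range(0, len(sequence) - word_length + 1, word_length):
        word = sequence[start : start + word_length]
        if set(word) <= _BASES:
            words.append(word)
    return words


@dataclass
class NGramModel:
    """Counts plus additive smoothing over fixed-length DNA words.

    Attributes
    ----------
    n
        History order: number of conditioning words (trigram model: n=3).
    word_length
        Word (segment) length in bases; the vocabulary is all
        ``4**word_length`` ACGT words.
    alpha
        Additive-smoothing pseudo-count per vocabulary word.
    context_counts
        Map from history tuple (length 0..n) to next-word counts.  Counts for
        every suffix of each observed history are stored, so backoff to the
        longest seen suffix is a dictionary lookup.
    context_totals
        Occurrence count of each history (equals the sum of its next-word
        counts).
    total_words_trained
        Number of words in the training corpus.
    """

    n: int = 3
    word_length: int = 7
    alpha: float = 0.01
    context_counts: dict[tuple[str, ...], dict[str, int]] = field(default_factory=dict)
    context_totals: dict[tuple[str, ...], int] = field(default_factory=dict)
    total_words_trained: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise NGramError("history order n must be >= 1")
        if not 4 <= self.word_length <= 8:
            raise NGramError("word_length must be in [4, 8]")
        if self.alpha <= 0:
            raise NGramError("smoothing alpha must be > 0")

    @property
    def vocabulary_size(self) -> int:
        return 4**self.word_length

    def word_log_prob(self, word: str, history: list[str] | tuple[str, ...]) -> float:
        """Natural-log probability of `word` given up to `n` history words.

        Uses the longest suffix of the history seen during training; an
        untrained model therefore collapses to the uniform distribution
        ``1 / 4**word_length``.
        """
        if len(word) != self.word_length or not set(word) <= _BASES:
            raise NGramError(
                f"word {word!r} is not a length-{self.word_length} ACGT word"
            )
        hist = tuple(history[-self.n :]) if history else ()
        totals = self.context_totals
        counts = self.context_counts
        alpha = self.alpha
        denom_pad = alpha * self.vocabulary_size
        for j in range(len(hist) + 1):
            h = hist[j:]
            total = totals.get(h)
            if total is None and h:
                continue
            total = total or 0
            count = counts.get(h, {}).get(word, 0) if total else 0
            return math.log((count + alpha) / (total + denom_pad))
        raise AssertionError("unreachable: empty history always matches")


@dataclass(frozen=True)
class UniformWordModel:
    """A language model assigning equal, independent probability to each of a
    fixed set of same-length words; its perplexity on any test sequence of
    those words is exactly the vocabulary size."""

    words: tuple[str, ...]
    n: int = 0

    def __post_init__(self) -> None:
        if not self.words:
            raise NGramError("empty vocabulary")
        lengths = {len(w) for w in self.words}
        if len(lengths) != 1:
            raise NGramError("vocabulary words must share one length")

    @property
    def word_length(self) -> int:
        return len(self.words[0])

    def word_log_prob(self, word: str, history) -> float:
        if word not in self.words:
            raise NGramError(f"word {word!r} not in vocabulary")
        return -math.log(len(self.words))


def train_ngram(
    rs: ReadSet,
    n: int = 3,
    word_length: int = 7,
    alpha: float = 0.01,
) -> NGramModel:
    """Count-train an :class:`NGramModel` on a read set.

    Each read is one sentence; no begin/end-of-sentence padding is used, so
    words near the sentence start condition on truncated histories.  Counts
    are exact multiplicities; training is deterministic.
    """
    model = NGramModel(n=n, word_length=word_length, alpha=alpha)
    counts = model.context_counts
    totals = model.context_totals
    m = 0
    for read in rs:
        words = segment_read(read.sequence, word_length)
        for i, w in enumerate(words):
            hist = tuple(words[max(0, i - n) : i])
            for j in range(len(hist) + 1):
                h = hist[j:]
                d = counts.get(h)
                if d is None:
                    d = counts[h] = {}
                d[w] = d.get(w, 0) + 1
                totals[h] = totals.get(h, 0) + 1
            m += 1
    if m == 0:
        raise NGramError("corpus yields no valid words after segmentation")
    model.total_words_trained = m
    return model


def corpus_perplexity(model, rs: ReadSet) -> float:
    """Average per-word perplexity of `rs` under `model`.

    Computes ``exp(-(1/m) * sum log P(word | history))`` over all words of all
    reads — the geometric-mean inverse probability of the test corpus.
    `model` may be any object exposing ``word_length``, ``n`` and
    ``word_log_prob``.
    """
    word_length = model.word_length
    n = model.n
    log_prob = model.word_log_prob
    log_sum = 0.0
    m = 0
    for read in rs:
        words = segment_read(read.sequence, word_length)
        for i, w in enumerate(words):
            log_sum += log_prob(w, words[max(0, i - n) : i])
        m += len(words)
    if m == 0:
        raise NGramError("no evaluable words in test corpus")
    return math.exp(-log_sum / m)


# --------------------------------------------------------------------------
# ARPA persistence
#
# Probabilities are written in standard ARPA sections (log10).  The backoff
# field of each history line carries log10 of the history's smoothed
# unseen-word probability alpha/(N_h + alpha*V); together with the metadata
# comment lines this lets the importer invert the smoothing formula and
# recover the exact integer counts, so round-trip perplexity is bit-stable.
# --------------------------------------------------------------------------

_LOG10 = math.log(10.0)


def export_arpa(model: NGramModel, path: str | Path) -> Path:
    """Write a trained model to `path` in ARPA n-gram format (log10 probs)."""
    if model.total_words_trained == 0:
        raise NGramError("refusing to export an untrained model")
    path = Path(path)
    V = model.vocabulary_size
    alpha = model.alpha
    by_order: dict[int, list[tuple[tuple[str, ...], str]]] = {}
    for hist, nexts in model.context_counts.items():
        order = len(hist) + 1
        for word in sorted(nexts):
            by_order.setdefault(order, []).append((hist, word))
    orders = sorted(by_order)
    with open(path, "w") as fh:
        fh.write("# kmertune additive-smoothing DNA n-gram model\n")
        fh.write(
            f"# order {model.n} word_length {model.word_length} "
            f"alpha {model.alpha!r} total_words {model.total_words_trained}\n\n"
        )
        fh.write("\\data\\\n")
        for order in orders:
            fh.write(f"ngram {order}={len(by_order[order])}\n")
        for order in orders:
            fh.write(f"\n\\{order}-grams:\n")
            for hist, word in sorted(by_order[order]):
                count = model.context_counts[hist][word]
                total = model.context_totals[hist]
                logp = math.log10((count + alpha) / (total + alpha * V))
                tokens = " ".join(hist + (word,))
                ngram = hist + (word,)
                if len(ngram) <= model.n and ngram in model.context_totals:
                    bow = math.log10(
                        alpha / (model.context_totals[ngram] + alpha * V)
                    )
                    fh.write(f"{logp:.12g}\t{tokens}\t{bow:.12g}\n")
                else:
                    fh.write(f"{logp:.12g}\t{tokens}\n")
        fh.write("\n\\end\\\n")
    return path


def import_arpa(path: str | Path) -> NGramModel:
    """Load a model written by :func:`export_arpa`.

    Validates the ``\\data\\`` entry counts against the listed n-grams and
    reconstructs the exact training counts from the smoothed probabilities.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    declared: dict[int, int] = {}
    sections: dict[int, list[tuple[float, tuple[str, ...], float | None]]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    it = iter(lines)
    for line in it:
        if line.startswith("#"):
            parts = line[1:].split()
            for key, val in zip(parts[::2], parts[1::2]):
                meta.setdefault(key, val)
        elif line.strip() == "\\data\\":
            break
    else:
        raise NGramError(f"{path}: missing \\data\\ header")
    current_order: int | None = None
    for line in it:
        line = line.strip()
        if not line:
            continue
        if line == "\\end\\":
            break
        if line.startswith("ngram "):
            spec_part = line[len("ngram ") :]
            order_s, _, count_s = spec_part.partition("=")
            declared[int(order_s)] = int(count_s)
        elif line.startswith("\\") and line.endswith("-grams:"):
            current_order = int(line[1:].split("-")[0])
            sections[current_order] = []
        else:
            if current_order is None:
                raise NGramError(f"{path}: entry outside any n-gram section")
            fields = line.split("\t") if "\t" in line else line.split()
            if "\t" in line:
                logp = float(fields[0])
                tokens = tuple(fields[1].split())
                bow = float(fields[2]) if len(fields) > 2 else None
            else:
                # whitespace-separated fallback: trailing float is a backoff
                logp = float(fields[0])
                rest = fields[1:]
                bow = None
                if len(rest) > current_order:
                    bow = float(rest[-1])
                    rest = rest[:-1]
                tokens = tuple(rest)
            if len(tokens) != current_order:
                raise NGramError(
                    f"{path}: {current_order}-gram entry has {len(tokens)} tokens"
                )
            sections[current_order].append((logp, tokens, bow))
    for order, count in declared.items():
        if len(sections.get(order, [])) != count:
            raise NGramError(
                f"{path}: \\data\\ declares {count} {order}-grams, "
                f"found {len(sections.get(order, []))}"
            )
    for order in sections:
        if order not in declared:
            raise NGramError(f"{path}: undeclared {order}-gram section")
    try:
        n = int(meta["order"])
        word_length = int(meta["word_length"])
        alpha = float(meta["alpha"])
        total_words = int(meta["total_words"])
    except KeyError as exc:
        raise NGramError(f"{path}: missing metadata field {exc}") from exc
    model = NGramModel(n=n, word_length=word_length, alpha=alpha)
    V = model.vocabulary_size
    totals: dict[tuple[str, ...], int] = {(): total_words}
    for order in sorted(sections):
        for logp, tokens, bow in sections[order]:
            hist, word = tokens[:-1], tokens[-1]
            if hist not in totals:
                raise NGramError(
                    f"{path}: history {' '.join(hist)!r} listed before its context"
                )
            N_h = totals[hist]
            count = round(10.0**logp * (N_h + alpha * V) - alpha)
            if count < 1:
                raise NGramError(f"{path}: non-positive count for {tokens!r}")
            model.context_counts.setdefault(hist, {})[word] = count
            if bow is not None:
                totals[tokens] = round(alpha / 10.0**bow - alpha * V)
    for hist, nexts in model.context_counts.items():
        model.context_totals[hist] = sum(nexts.values())
    # cross-check recovered totals against the backoff-derived ones
    for hist, total in model.context_totals.items():
        if hist in totals and totals[hist] != total:
            raise NGramError(
                f"{path}: count mismatch for history {' '.join(hist)!r}"
            )
    model.total_words_trained = total_words
    if model.context_totals.get((), 0) != total_words:
        raise NGramError(f"{path}: unigram counts do not sum to total_words")
    return model
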