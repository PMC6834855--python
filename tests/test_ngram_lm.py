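import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kmertune.ngram_lm import (
    NGramError,
    NGramModel,
    UniformWordModel,
    corpus_perplexity,
    export_arpa,
    import_arpa,
    segment_read,
    train_ngram,
)
from kmertune.readset_io import Read, ReadSet
from kmertune.synthetic_errors import ErrorSpec, generate_genome, inject_dataset, simulate_reads

from conftest import make_readset


def brute_force_perplexity(train_rs, test_rs, n, word_length, alpha):
    """Literal inverse-probability evaluation: recount everything from
    scratch with plain loops, multiply the per-word probabilities, and take
    the m-th root.  Independent of the package's count structures."""
    counts = {}
    for read in train_rs:
        words = [
            read.sequence[i : i + word_length]
            for i in range(0, len(read.sequence) - word_length + 1, word_length)
        ]
        words = [w for w in words if set(w) <= set("ACGT")]
        for i, w in enumerate(words):
            hist = tuple(words[max(0, i - n) : i])
            for j in range(len(hist) + 1):
                counts.setdefault(hist[j:], []).append(w)
    V = 4**word_length
    log_sum, m = 0.0, 0
    for read in test_rs:
        words = [
            read.sequence[i : i + word_length]
            for i in range(0, len(read.sequence) - word_length + 1, word_length)
        ]
        words = [w for w in words if set(w) <= set("ACGT")]
        for i, w in enumerate(words):
            hist = tuple(words[max(0, i - n) : i])
            for j in range(len(hist) + 1):
                h = hist[j:]
                if h in counts or h == ():
                    seen = counts.get(h, [])
                    prob = (seen.count(w) + alpha) / (len(seen) + alpha * V)
                    break
            log_sum += math.log(prob)
            m += 1
    return (1.0 / math.exp(log_sum)) ** (1.0 / m)


@pytest.mark.parametrize(
    "sequence,word_length,expected",
    [
        ("ACGTACGTACGT", 4, ["ACGT", "ACGT", "ACGT"]),
        ("ACGTACGTACGT", 7, ["ACGTACG"]),  # trailing TACGT dropped
        ("ACGNACGT", 4, ["ACGT"]),  # first window holds N, positions kept
        ("ACG", 4, []),
    ],
)
def test_segmentation_tiles_from_position_zero(sequence, word_length, expected):
    assert segment_read(sequence, word_length) == expected


@given(seq=st.text(alphabet="ACGTN", min_size=0, max_size=60), L=st.integers(1, 9))
def test_segmentation_properties(seq, L):
    words = segment_read(seq, L)
    assert all(len(w) == L and set(w) <= set("ACGT") for w in words)
    assert len(words) <= len(seq) // L


def test_training_hand_count():
    model = train_ngram(make_readset(["AAAAAAAA"]), n=1, word_length=4)
    assert model.context_counts[("AAAA",)] == {"AAAA": 1}
    assert model.context_counts[()] == {"AAAA": 2}
    assert model.total_words_trained == 2


def test_training_is_deterministic():
    rs = make_readset(["ACGTACGTACGTACGT", "TTTTACGTACGTCCCC"])
    assert train_ngram(rs, n=2, word_length=4) == train_ngram(rs, n=2, word_length=4)


def test_training_empty_corpus_rejected():
    with pytest.raises(NGramError):
        train_ngram(make_readset(["NNNNNNNN"]), n=1, word_length=4)


def test_untrained_model_is_uniform():
    model = NGramModel(n=1, word_length=4)
    assert math.isclose(model.word_log_prob("ACGT", []), math.log(1 / 256))


def test_smoothing_formula_direct_substitution():
    model = train_ngram(make_readset(["AAAAAAAA"]), n=1, word_length=4, alpha=0.01)
    got = model.word_log_prob("AAAA", ["AAAA"])
    assert math.isclose(got, math.log((1 + 0.01) / (1 + 0.01 * 256)), rel_tol=1e-12)


def test_conditional_distributions_normalize(rng):
    rs = make_readset(
        "".join(row) for row in np.array(list("ACGT"))[rng.integers(0, 4, (30, 24))]
    )
    model = train_ngram(rs, n=2, word_length=4)
    vocab = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
    for history in ([], ["ACGT"], ["AAAA", "ACGT"], ["TTTT", "GGGG"]):
        total = sum(math.exp(model.word_log_prob(w, history)) for w in vocab)
        assert abs(total - 1.0) < 1e-9


def test_degenerate_single_word_model_has_unit_perplexity():
    model = UniformWordModel(("ACGT",))
    assert corpus_perplexity(model, make_readset(["ACGTACGTACGT"])) == pytest.approx(1.0)


def test_perplexity_matches_bruteforce_on_toy_corpus():
    train = make_readset(["ACGTACGTTGCATGCA", "ACGTACGTACGTACGT", "TTTTGGGGCCCCAAAA"])
    test = make_readset(["ACGTACGTTGCAGGGG", "CCCCAAAATTTTACGT"])
    model = train_ngram(train, n=3, word_length=4, alpha=0.01)
    expected = brute_force_perplexity(train, test, 3, 4, 0.01)
    assert corpus_perplexity(model, test) == pytest.approx(expected, rel=1e-9)


def test_perplexity_increases_with_injected_substitutions():
    """Direction check: clean held-out reads score below 1-substitution reads,
    which score below 5-substitution reads, for every tested seed."""
    for seed in (0, 1):
        genome = generate_genome(20_000, seed)
        dataset = simulate_reads(genome, 30, 100, 0.0, seed=seed + 100)
        model = train_ngram(dataset.reads)
        held_out = ReadSet(dataset.reads.reads[:400])
        one = inject_dataset(
            held_out,
            ErrorSpec("substitution", "fixed", fixed_count=1, seed=seed + 1),
        )
        five = inject_dataset(
            held_out,
            ErrorSpec("substitution", "fixed", fixed_count=5, seed=seed + 2),
        )
        p0 = corpus_perplexity(model, held_out)
        p1 = corpus_perplexity(model, one)
        p5 = corpus_perplexity(model, five)
        assert p0 < p1 < p5


def test_arpa_round_trip_is_exact(tmp_path):
    genome = generate_genome(3_000, 5)
    dataset = simulate_reads(genome, 6, 60, 0.01, seed=6)
    model = train_ngram(dataset.reads, n=3, word_length=4)
    path = tmp_path / "model.arpa"
    export_arpa(model, path)
    back = import_arpa(path)
    assert back.context_counts == model.context_counts
    assert back.context_totals == model.context_totals
    assert corpus_perplexity(back, dataset.reads) == pytest.approx(
        corpus_perplexity(model, dataset.reads), rel=1e-9
    )


def test_arpa_count_mismatch_rejected(tmp_path):
    model = train_ngram(make_readset(["ACGTACGTACGTACGT"]), n=1, word_length=4)
    path = tmp_path / "model.arpa"
    export_arpa(model, path)
    text = path.read_text().replace("ngram 1=", "ngram 1=9")
    bad = tmp_path / "bad.arpa"
    bad.write_text(text)
    with pytest.raises(NGramError):
        import_arpa(bad)


def test_arpa_missing_header_rejected(tmp_path):
    bad = tmp_path / "nohdr.arpa"
    bad.write_text("\\1-grams:\n-0.5 ACGT\n\\end\\\n")
    with pytest.raises(NGramError):
        import_arpa(bad)


def test_untrained_model_export_rejected(tmp_path):
    with pytest.raises(NGramError):
        export_arpa(NGramModel(n=1, word_length=4), tmp_path / "x.arpa")
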