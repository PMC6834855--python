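import math

import pytest

from kmertune.ngram_lm import train_ngram
from kmertune.readset_io import ReadSet
from kmertune.spectral_corrector import builtin_corrector
from kmertune.synthetic_errors import generate_genome, simulate_reads
from kmertune.tuner import (
    EvaluationFailed,
    TuningConfig,
    TuningError,
    default_k_range,
    evaluate_config,
    find_optimal_k,
    tune,
)


def profile_fn(table):
    return lambda v: table[v]


def cfg_for(table, **kwargs):
    kwargs.setdefault("max_iterations", 50)
    return TuningConfig(values=sorted(table), **kwargs)


def test_walk_descends_to_local_minimum():
    table = {10: 5.0, 11: 4.0, 12: 3.5, 13: 3.7}
    best, trace = find_optimal_k(profile_fn(table), cfg_for(table), 10)
    assert best == 12
    assert [step[1] for step in trace] == [10, 11, 12]


def test_monotone_profile_reaches_boundary():
    table = {k: 100.0 - k for k in range(10, 21)}
    best, _ = find_optimal_k(profile_fn(table), cfg_for(table), 10)
    assert best == 20


def test_bimodal_profile_returns_nearby_local_minimum():
    """Documents the local-minimum behavior that motivates multi-start."""
    table = {11: 4.0, 12: 3.5, 13: 4.5, 19: 4.2, 20: 3.0, 21: 4.4}
    cfg = TuningConfig(values=[11, 12, 13, 19, 20, 21], max_iterations=50)
    best, _ = find_optimal_k(profile_fn(table), cfg, 11)
    assert best == 12


def test_plateau_terminates():
    table = {k: 1.0 for k in range(5)}
    best, trace = find_optimal_k(profile_fn(table), cfg_for(table), 2)
    assert best in table
    assert len(trace) == 1  # flat: current <= both neighbors immediately


def test_ties_break_toward_smaller_value():
    table = {1: 5.0, 2: 6.0, 3: 5.0}
    best, _ = find_optimal_k(profile_fn(table), cfg_for(table), 2)
    assert best == 1


def test_start_outside_grid_rejected():
    with pytest.raises(TuningError):
        find_optimal_k(profile_fn({1: 1.0}), TuningConfig(values=[1]), 99)


def test_failed_values_excluded_from_walk():
    def f(v):
        if v == 12:
            raise EvaluationFailed("boom")
        return {10: 5.0, 11: 4.0, 13: 9.0}[v]

    cfg = TuningConfig(values=[10, 11, 12, 13], max_iterations=50)
    best, _ = find_optimal_k(f, cfg, 10)
    assert best == 11


def test_default_k_range_tracks_read_length():
    assert default_k_range(100) == (10, 32)
    assert default_k_range(30) == (10, 29)


class CountingCorrector:
    def __init__(self, inner=None):
        self.calls = 0
        self.inner = inner

    def __call__(self, rs, value):
        self.calls += 1
        return self.inner(rs, value) if self.inner else rs


@pytest.fixture(scope="module")
def small_fixture():
    genome = generate_genome(20_000, 31)
    dataset = simulate_reads(genome, 40, 100, 0.02, seed=32)
    model = train_ngram(dataset.reads)
    return genome, dataset, model


def test_identity_corrector_gives_identical_perplexities(small_fixture):
    _, dataset, model = small_fixture
    sample = ReadSet(dataset.reads.reads[:500])
    ec = CountingCorrector()
    p1 = evaluate_config(model, ec, sample, 10)
    p2 = evaluate_config(model, ec, sample, 25)
    assert p1 == p2


def test_memoization_skips_repeat_corrector_calls(small_fixture):
    _, dataset, model = small_fixture
    sample = ReadSet(dataset.reads.reads[:500])
    ec = CountingCorrector()
    memo = {}
    evaluate_config(model, ec, sample, 10, memo=memo)
    evaluate_config(model, ec, sample, 10, memo=memo)
    assert ec.calls == 1


def test_degenerate_range_single_evaluation(small_fixture):
    _, dataset, model = small_fixture
    rs = ReadSet(dataset.reads.reads[:600])
    ec = CountingCorrector(builtin_corrector())
    cfg = TuningConfig(lower_bound=15, upper_bound=15, genome_length=20_000, seed=1)
    result, corrected = tune(rs, ec, cfg, lm=model)
    assert result.selected_value == 15
    assert result.evaluations == 1
    assert len(corrected) == len(rs)


def test_tune_matches_grid_scan_and_respects_budget(small_fixture):
    """Single-start hill climb lands on the walk's minimum, which on this
    unimodal-enough profile equals the brute-force grid argmin; distinct
    corrector invocations never exceed the grid size."""
    genome, dataset, model = small_fixture
    ks = list(range(10, 25, 2))
    ec = CountingCorrector(builtin_corrector())
    cfg = TuningConfig(values=ks, genome_length=20_000, seed=2, max_iterations=50)
    result, corrected = tune(dataset.reads, ec, cfg, lm=model)
    sample_calls = ec.calls - 1  # final full-dataset correction
    assert sample_calls <= len(ks)
    assert result.evaluations == len(result.perplexity_by_value) <= len(ks)
    # walk minimum: no evaluated neighbor beats the selection
    prof = result.perplexity_by_value
    best = result.selected_value
    assert prof[best] == min(prof.values())
    # and the full scan agrees (profile is unimodal here)
    full = {
        k: evaluate_config(model, builtin_corrector(), tune_sample(dataset, cfg), k)
        for k in ks
    }
    assert min(full, key=full.get) == best


def tune_sample(dataset, cfg):
    from kmertune.sampling import required_sample_size, subsample

    n = required_sample_size(cfg.sample_coverage_target, cfg.genome_length, 100)
    return subsample(dataset.reads, n, cfg.seed)


def test_two_starts_share_memo(small_fixture):
    _, dataset, model = small_fixture
    ks = list(range(10, 25, 2))
    ec_single = CountingCorrector(builtin_corrector())
    cfg1 = TuningConfig(values=ks, genome_length=20_000, seed=2, max_iterations=50)
    tune(dataset.reads, ec_single, cfg1, lm=model)
    ec_double = CountingCorrector(builtin_corrector())
    cfg2 = TuningConfig(
        values=ks, genome_length=20_000, seed=2, max_iterations=50, starts=[12, 20]
    )
    tune(dataset.reads, ec_double, cfg2, lm=model)
    assert ec_double.calls < 2 * ec_single.calls


def test_all_starts_failing_raises(small_fixture):
    _, dataset, model = small_fixture

    def broken(rs, value):
        raise RuntimeError("tool crashed")

    cfg = TuningConfig(lower_bound=10, upper_bound=12, seed=1, max_iterations=5)
    with pytest.raises(TuningError):
        tune(ReadSet(dataset.reads.reads[:50]), broken, cfg, lm=model)


def test_failing_value_recorded_and_walk_continues(small_fixture):
    _, dataset, model = small_fixture
    inner = builtin_corrector()

    def flaky(rs, value):
        if value == 14:
            raise RuntimeError("no output")
        return inner(rs, value)

    cfg = TuningConfig(
        values=[12, 14, 16, 18], genome_length=20_000, seed=3, max_iterations=50,
        starts=[16],
    )
    result, _ = tune(dataset.reads, flaky, cfg, lm=model)
    assert 14 in result.failures
    assert 14 not in result.perplexity_by_value
    assert result.selected_value != 14
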