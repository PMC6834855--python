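"""Perplexity-guided hill-climbing search for corrector parameters.

The objective is

    k_opt = argmin_k  Perplexity(LM, correct(sample, k))

with the language model trained once on the full *uncorrected* dataset: a
well-corrected sample looks more like the dominant (correct) text the model
memorized, so its perplexity drops.  Because the parameter is discrete the
objective has no derivative; a simple hill climb evaluates the current value
and its two δ-neighbors, moves to a strictly lower neighbor (ties toward the
smaller value), and stops when the current value is at least as good as both
neighbors or the iteration cap is reached.  Multiple starts share one memo
table, so the total number of corrector invocations never exceeds the grid
size, and the global best over everything evaluated is returned.

Correction runs on a coverage-targeted subsample (30X by default); N-gram
perplexity is computed on the whole corrected sample, RNN perplexity on a
fixed uniform subsample of it (min of 50,000 reads and 1% of the sample, the
same read indices at every parameter value so comparisons are paired).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .char_rnn_lm import RNNConfig, RNNModel, rnn_perplexity, train_rnn
from .ngram_lm import corpus_perplexity, train_ngram
from .readset_io import ReadSet
from .sampling import required_sample_size, subsample

__all__ = [
    "TuningError",
    "EvaluationFailed",
    "TuningConfig",
    "TuningResult",
    "evaluate_config",
    "find_optimal_k",
    "tune",
    "default_k_range",
]


class TuningError(RuntimeError):
    """No evaluable parameter value, or an invalid search configuration."""


class EvaluationFailed(RuntimeError):
    """A corrector invocation failed for one parameter value; the value is
    recorded as non-evaluable and excluded from the walk."""


def default_k_range(read_length: int) -> tuple[int, int]:
    """Default k search range when a tool does not declare one:
    [10, min(32, read_length - 1)]."""
    return 10, min(32, read_length - 1)


@dataclass
class TuningConfig:
    """Search-space and evaluation settings for :func:`tune`.

    Either ``lower_bound``/``upper_bound`` (an inclusive integer range) or an
    explicit ordered ``values`` list (e.g. multiplicative genome-length grids)
    defines the grid; ``delta`` is the neighborhood radius in grid steps.
    ``starts`` defaults to the single grid midpoint.
    """

    lower_bound: int | None = None
    upper_bound: int | None = None
    values: Sequence | None = None
    delta: int = 1
    starts: Sequence | None = None
    max_iterations: int = 20
    lm_variant: str = "ngram"
    sample_coverage_target: float = 30.0
    genome_length: int | None = None
    seed: int = 0
    rnn_score_max_reads: int = 50_000
    rnn_score_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.values is None:
            if self.lower_bound is None or self.upper_bound is None:
                raise TuningError("either bounds or an explicit value list is required")
            if self.lower_bound > self.upper_bound:
                raise TuningError("lower_bound must not exceed upper_bound")
        elif len(self.values) == 0:
            raise TuningError("explicit value list must be non-empty")
        if self.delta < 1:
            raise TuningError("delta must be >= 1")
        if self.max_iterations < 1:
            raise TuningError("max_iterations must be >= 1")
        if self.lm_variant not in ("ngram", "rnn"):
            raise TuningError(f"unknown lm_variant {self.lm_variant!r}")
        grid = self.grid()
        for start in self.starts or []:
            if start not in grid:
                raise TuningError(f"start {start!r} outside the search grid")

    def grid(self) -> list:
        if self.values is not None:
            return list(self.values)
        return list(range(self.lower_bound, self.upper_bound + 1))


@dataclass
class TuningResult:
    """Outcome of a tuning session.

    ``selected_value`` minimizes perplexity over everything evaluated;
    ``evaluations`` counts distinct successfully scored parameter values
    (= corrector invocations that produced a perplexity); ``failures`` maps
    non-evaluable values to their error messages; ``trace`` is the ordered
    walk history of every start: (iteration, current value, neighbor
    perplexities).
    """

    selected_value: object
    perplexity_by_value: dict
    evaluations: int
    trace: list = field(default_factory=list)
    failures: dict = field(default_factory=dict)


def _score_perplexity(lm, corrected: ReadSet, cfg: TuningConfig) -> float:
    if isinstance(lm, RNNModel):
        n = min(cfg.rnn_score_max_reads, max(1, int(len(corrected) * cfg.rnn_score_fraction)))
        return rnn_perplexity(lm, subsample(corrected, n, cfg.seed))
    return corpus_perplexity(lm, corrected)


def evaluate_config(
    lm,
    ec: Callable[[ReadSet, object], ReadSet],
    sample: ReadSet,
    value,
    cfg: TuningConfig | None = None,
    memo: dict | None = None,
    failures: dict | None = None,
) -> float:
    """Correct `sample` at `value` with `ec` and score it under `lm`.

    Results are memoized per value when a `memo` dict is supplied (one per
    tuning session): a repeat evaluation performs zero corrector invocations.
    Corrector failures raise :class:`EvaluationFailed` and are remembered in
    `failures` so the command is not retried.
    """
    cfg = cfg or TuningConfig(lower_bound=0, upper_bound=0)
    if memo is not None and value in memo:
        return memo[value]
    if failures is not None and value in failures:
        raise EvaluationFailed(failures[value])
    try:
        corrected = ec(sample, value)
        perplexity = _score_perplexity(lm, corrected, cfg)
    except EvaluationFailed:
        raise
    except Exception as exc:
        message = f"corrector failed at value {value!r}: {exc}"
        if failures is not None:
            failures[value] = message
        raise EvaluationFailed(message) from exc
    if memo is not None:
        memo[value] = perplexity
    return perplexity


def find_optimal_k(
    f: Callable[[object], float], cfg: TuningConfig, start
) -> tuple[object, list]:
    """Hill-climb `f` over the grid from `start`; return (best value, trace).

    Evaluates the current value and its ±δ neighbors (values outside the
    grid count as +inf), moves to the strictly lower neighbor with ties
    broken toward the smaller value, and terminates when the current value is
    at least as good as both neighbors or after ``max_iterations``.  A value
    whose evaluation fails is treated as +inf and never selected.
    """
    grid = cfg.grid()
    try:
        cursor = grid.index(start)
    except ValueError:
        raise TuningError(f"start {start!r} outside the search grid") from None
    seen: dict[int, float] = {}

    def F(i: int) -> float:
        if not 0 <= i < len(grid):
            return math.inf
        if i not in seen:
            try:
                seen[i] = f(grid[i])
            except EvaluationFailed:
                seen[i] = math.inf
        return seen[i]

    trace: list[tuple[int, object, dict]] = []
    for iteration in range(cfg.max_iterations):
        here = F(cursor)
        left = F(cursor - cfg.delta)
        right = F(cursor + cfg.delta)
        neighbors = {}
        if cursor - cfg.delta >= 0:
            neighbors[grid[cursor - cfg.delta]] = left
        if cursor + cfg.delta < len(grid):
            neighbors[grid[cursor + cfg.delta]] = right
        trace.append((iteration, grid[cursor], neighbors))
        if here <= left and here <= right:
            break
        cursor = cursor - cfg.delta if left <= right else cursor + cfg.delta
    finite = {i: v for i, v in seen.items() if math.isfinite(v)}
    if not finite:
        raise TuningError("no evaluable value on the walk")
    best_index = min(finite, key=lambda i: (finite[i], i))
    return grid[best_index], trace


def tune(
    rs_full: ReadSet,
    ec: Callable[[ReadSet, object], ReadSet],
    cfg: TuningConfig,
    lm=None,
    ngram_order: int = 3,
    word_length: int = 7,
    alpha: float = 0.01,
    rnn_config: RNNConfig | None = None,
) -> tuple[TuningResult, ReadSet]:
    """Full tuning session: train LM, subsample, search, correct everything.

    Trains the language model on the complete uncorrected dataset (unless a
    pre-trained `lm` is supplied), draws the coverage-targeted sample, runs
    the hill climb from every start over one shared memo table, selects the
    global perplexity minimum among all evaluated values, and corrects the
    complete dataset at that value.
    """
    if len(rs_full) == 0:
        raise TuningError("cannot tune on an empty read set")
    if lm is None:
        if cfg.lm_variant == "ngram":
            lm = train_ngram(rs_full, n=ngram_order, word_length=word_length, alpha=alpha)
        else:
            lm = train_rnn(rs_full, rnn_config or RNNConfig(seed=cfg.seed))
    if cfg.genome_length is not None:
        read_length = rs_full.declared_read_length or rs_full.modal_read_length()
        n_sample = required_sample_size(
            cfg.sample_coverage_target, cfg.genome_length, read_length
        )
        sample = subsample(rs_full, n_sample, cfg.seed)
    else:
        sample = rs_full  # genome size unknown: whole-dataset rule
    memo: dict = {}
    failures: dict = {}

    def f(value) -> float:
        return evaluate_config(lm, ec, sample, value, cfg, memo=memo, failures=failures)

    grid = cfg.grid()
    starts = list(cfg.starts) if cfg.starts else [grid[len(grid) // 2]]
    trace: list = []
    for start in starts:
        try:
            _, walk = find_optimal_k(f, cfg, start)
        except TuningError:
            continue  # every value on this walk failed; other starts may work
        trace.extend(walk)
    if not memo:
        raise TuningError(f"no start produced an evaluable value: {failures}")
    order = {v: i for i, v in enumerate(grid)}
    selected = min(memo, key=lambda v: (memo[v], order[v]))
    corrected_full = ec(rs_full, selected)
    result = TuningResult(
        selected_value=selected,
        perplexity_by_value=dict(memo),
        evaluations=len(memo),
        trace=trace,
        failures=dict(failures),
    )
    return result, corrected_full
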