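"""Hermetic end-to-end benchmark of the perplexity surrogate.

`run_fixture_grid` builds the standard synthetic fixture — a 100 kb uniform
random genome sequenced at 50X with 100 bp reads and a 2% per-base
substitution rate — trains a trigram language model on the noisy reads,
corrects a 30X subsample with the built-in spectral corrector at every k on
a grid, and records each corrected sample's perplexity alongside its
ground-truth base accuracy and EC gain.  This is the scaled-down analog of
sweeping a corrector's k against a reference-aligned quality metric, and is
what the correlation and rank checks run on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluation import score_correction
from .ngram_lm import corpus_perplexity, train_ngram
from .readset_io import ReadSet
from .sampling import required_sample_size, subsample
from .spectral_corrector import SpectralParams, correct_reads
from .synthetic_errors import SimulatedDataset, generate_genome, simulate_reads

__all__ = ["GridRunResult", "run_fixture_grid", "FIXTURE_KS"]

#: Default k grid of the standard fixture.
FIXTURE_KS: tuple[int, ...] = tuple(range(8, 31, 2))


@dataclass
class GridRunResult:
    """Per-k perplexity and truth-based quality over one fixture run."""

    seed: int
    ks: list[int]
    perplexities: list[float]
    accuracies: list[float]
    gains: list[float]
    uncorrected_perplexity: float
    uncorrected_accuracy: float
    dataset: SimulatedDataset | None = None
    sample: ReadSet | None = None
    corrected: dict[int, ReadSet] = field(default_factory=dict)

    def accuracy_rank(self, k: int) -> int:
        """1-based rank of `k` when the grid is ordered by decreasing accuracy."""
        order = sorted(self.ks, key=lambda kk: -self.accuracies[self.ks.index(kk)])
        return order.index(k) + 1


def run_fixture_grid(
    seed: int,
    genome_length: int = 100_000,
    coverage: float = 50.0,
    read_length: int = 100,
    sub_rate: float = 0.02,
    ks: Sequence[int] = FIXTURE_KS,
    solid_threshold: int = 2,
    max_corrections: int = 4,
    sample_coverage: float = 30.0,
    ngram_order: int = 3,
    word_length: int = 7,
    alpha: float = 0.01,
    keep_corrected: bool = False,
    keep_dataset: bool = True,
) -> GridRunResult:
    """Run the fixture sweep; see the module docstring for the protocol.

    All randomness (genome, read starts, substitutions, subsampling) derives
    from `seed`.  Set `keep_corrected` to retain the per-k corrected samples
    (e.g. for re-scoring under a second language model).
    """
    child_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(3) % (2**31)]
    genome = generate_genome(genome_length, seed=child_seeds[0])
    dataset = simulate_reads(
        genome, coverage, read_length, per_base_sub_rate=sub_rate, seed=child_seeds[1]
    )
    lm = train_ngram(dataset.reads, n=ngram_order, word_length=word_length, alpha=alpha)
    n_sample = required_sample_size(sample_coverage, genome_length, read_length)
    sample = subsample(dataset.reads, n_sample, seed=child_seeds[2])
    perplexities: list[float] = []
    accuracies: list[float] = []
    gains: list[float] = []
    corrected_by_k: dict[int, ReadSet] = {}
    for k in ks:
        params = SpectralParams(
            k=k,
            solid_threshold=solid_threshold,
            max_corrections_per_read=max_corrections,
        )
        corrected = correct_reads(sample, params)
        perplexities.append(corpus_perplexity(lm, corrected))
        report = score_correction(sample, corrected, dataset)
        accuracies.append(report.base_accuracy)
        gains.append(report.ec_gain)
        if keep_corrected:
            corrected_by_k[k] = corrected
    uncorrected = score_correction(sample, sample, dataset)
    return GridRunResult(
        seed=seed,
        ks=list(ks),
        perplexities=perplexities,
        accuracies=accuracies,
        gains=gains,
        uncorrected_perplexity=corpus_perplexity(lm, sample),
        uncorrected_accuracy=uncorrected.base_accuracy,
        dataset=dataset if keep_dataset else None,
        sample=sample if keep_dataset else None,
        corrected=corrected_by_k,
    )
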