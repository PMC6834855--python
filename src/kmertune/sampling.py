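"""Coverage-targeted subsampling of read datasets for the tuning loop.

The tuner corrects a subsample rather than the full dataset; the subsample
size is chosen from the Lander–Waterman coverage identity C = N*L/G so the
sample retains at least the target coverage (30X by default), below which
solid and insolid k-mer count distributions blur together and spectrum-based
correctors stop correcting.  Datasets with less than the target coverage are
used whole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .readset_io import ReadSet

__all__ = ["SamplingError", "SamplingPlan", "required_sample_size", "subsample", "plan_sample"]


class SamplingError(ValueError):
    """Non-positive sizing inputs or an empty read set."""


@dataclass(frozen=True)
class SamplingPlan:
    """A resolved subsampling decision: how many reads to draw and why."""

    genome_length: int
    read_length: int
    coverage_target: float
    dataset_reads: int
    sample_reads: int
    seed: int


def required_sample_size(coverage: float, genome_length: int, read_length: int) -> int:
    """Reads needed for `coverage`-fold coverage of a `genome_length` genome:
    ceil(C * G / L) from the Lander–Waterman identity C = N*L/G."""
    if coverage <= 0 or genome_length <= 0 or read_length <= 0:
        raise SamplingError("coverage, genome_length and read_length must be positive")
    return math.ceil(coverage * genome_length / read_length)


def subsample(rs: ReadSet, n: int, seed: int = 0) -> ReadSet:
    """Uniform sample of `n` reads without replacement, original order kept.

    Deterministic per `seed`; if ``n >= len(rs)`` the whole set is returned
    unchanged (whole-dataset rule for under-covered inputs).
    """
    if len(rs) == 0:
        raise SamplingError("cannot subsample an empty read set")
    if n < 1:
        raise SamplingError("sample size must be >= 1")
    if n >= len(rs):
        return rs
    rng = np.random.default_rng(seed)
    indices = np.sort(rng.choice(len(rs), size=n, replace=False))
    return ReadSet([rs[int(i)] for i in indices], source_path=rs.source_path)


def plan_sample(
    rs: ReadSet,
    genome_length: int,
    coverage_target: float = 30.0,
    seed: int = 0,
) -> SamplingPlan:
    """Resolve the subsample size for `rs` against a known genome length."""
    read_length = rs.declared_read_length or rs.modal_read_length()
    needed = required_sample_size(coverage_target, genome_length, read_length)
    return SamplingPlan(
        genome_length=genome_length,
        read_length=read_length,
        coverage_target=coverage_target,
        dataset_reads=len(rs),
        sample_reads=min(len(rs), needed),
        seed=seed,
    )
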