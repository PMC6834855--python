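"""Synthetic genome/read simulator and error injection.

This is the hermetic data source for validating the perplexity–error-rate
relationship: uniform-coverage forward-strand reads are drawn from a random
(or supplied) genome, with per-read ground truth retained, and three error
models can then be injected:

* **deletion** — remove a segment of ``deletion_length`` bases at an index
  drawn uniformly from the valid range;
* **insertion** — insert ``insertion_length`` uniform-random bases at a
  uniform index;
* **substitution** — replace ``substitution_count`` distinct uniform
  positions with bases drawn uniformly over all four (so one in four
  substitutions silently preserves the base);
* **mixture** — the error type is drawn equiprobably per event.

Error mass per read is set by the rate class: ``low`` draws the per-read
event count uniformly from {1..5}, ``high`` from {6..10} (single-base events,
so the class is the number of error bases per read), and ``fixed`` applies
exactly ``fixed_count`` events of the configured magnitudes.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .readset_io import Read, ReadSet

__all__ = [
    "SyntheticError",
    "ErrorSpec",
    "TruthRecord",
    "SimulatedDataset",
    "generate_genome",
    "simulate_reads",
    "inject_errors",
    "inject_dataset",
    "write_truth",
    "load_truth",
]

_BASES = "ACGT"
_DECODE = np.frombuffer(_BASES.encode(), dtype=np.uint8)
_ERROR_TYPES = ("deletion", "insertion", "substitution", "mixture")
_RATE_CLASSES = ("low", "high", "fixed")


class SyntheticError(ValueError):
    """Invalid simulation or injection parameters."""


@dataclass(frozen=True)
class ErrorSpec:
    """Error-injection recipe: which error type, how much per read, and the
    magnitude of each event."""

    error_type: str
    rate_class: str = "low"
    fixed_count: int = 1
    deletion_length: int = 1
    insertion_length: int = 1
    substitution_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.error_type not in _ERROR_TYPES:
            raise SyntheticError(f"unknown error_type {self.error_type!r}")
        if self.rate_class not in _RATE_CLASSES:
            raise SyntheticError(f"unknown rate_class {self.rate_class!r}")
        if self.fixed_count < 0:
            raise SyntheticError("fixed_count must be >= 0")
        if min(self.deletion_length, self.insertion_length, self.substitution_count) < 1:
            raise SyntheticError("event magnitudes must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """Error-free sequence of a simulated read and its 0-based forward-strand
    genomic start coordinate."""

    start: int
    sequence: str


@dataclass
class SimulatedDataset:
    genome: str
    reads: ReadSet
    truth: dict[str, TruthRecord] = field(default_factory=dict)


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def generate_genome(length: int, seed: int = 0) -> str:
    """An i.i.d. uniform ACGT string of `length` bases, deterministic per seed."""
    if length < 1:
        raise SyntheticError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    return _decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def simulate_reads(
    genome: str,
    coverage: float,
    read_length: int,
    per_base_sub_rate: float = 0.0,
    seed: int = 0,
    id_prefix: str = "sim",
) -> SimulatedDataset:
    """Uniform-start shotgun reads from `genome` with i.i.d. substitutions.

    Draws ``N = ceil(coverage * G / L)`` forward-strand reads with starts
    uniform on {0..G-L} (with replacement); each base is substituted with
    probability `per_base_sub_rate`, uniformly among the three other bases.
    Per-read truth records are kept.
    """
    G = len(genome)
    if read_length > G:
        raise SyntheticError(f"read_length {read_length} exceeds genome length {G}")
    if read_length < 1 or coverage <= 0:
        raise SyntheticError("read_length and coverage must be positive")
    if not 0.0 <= per_base_sub_rate < 1.0:
        raise SyntheticError("per_base_sub_rate must lie in [0, 1)")
    n_reads = math.ceil(coverage * G / read_length)
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, G - read_length + 1, size=n_reads)
    gcodes = np.frombuffer(genome.encode(), dtype=np.uint8)
    lookup = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lookup[ord(b)] = i
    gcodes = lookup[gcodes]
    reads: list[Read] = []
    truth: dict[str, TruthRecord] = {}
    width = len(str(n_reads - 1))
    for i in range(n_reads):
        s = int(starts[i])
        clean = gcodes[s : s + read_length]
        if per_base_sub_rate > 0.0:
            mask = rng.random(read_length) < per_base_sub_rate
            if mask.any():
                shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
                noisy = clean.copy()
                noisy[mask] = (noisy[mask] + shifts) % 4
            else:
                noisy = clean
        else:
            noisy = clean
        rid = f"{id_prefix}_{i:0{width}d}"
        reads.append(Read(rid, _decode(noisy)))
        truth[rid] = TruthRecord(s, _decode(clean))
    return SimulatedDataset(genome=genome, reads=ReadSet(reads), truth=truth)


def _event_count(spec: ErrorSpec, rng: np.random.Generator) -> int:
    if spec.rate_class == "low":
        return int(rng.integers(1, 6))
    if spec.rate_class == "high":
        return int(rng.integers(6, 11))
    return spec.fixed_count


def inject_errors(read: Read, spec: ErrorSpec, rng: np.random.Generator) -> Read:
    """Apply one read's worth of synthetic errors; deterministic per rng state.

    Length contracts: a deletion event shortens the read by
    ``deletion_length``, an insertion lengthens it by ``insertion_length``,
    substitution preserves length with Hamming distance at most
    ``substitution_count`` per event.
    """
    seq = list(read.sequence)
    for _ in range(_event_count(spec, rng)):
        etype = spec.error_type
        if etype == "mixture":
            etype = ("deletion", "insertion", "substitution")[int(rng.integers(3))]
        L = len(seq)
        if etype == "deletion":
            d = spec.deletion_length
            if L <= d:
                raise SyntheticError(
                    f"cannot delete {d} bases from a {L}-base read {read.identifier!r}"
                )
            pos = int(rng.integers(0, L - d + 1))
            del seq[pos : pos + d]
        elif etype == "insertion":
            I = spec.insertion_length
            pos = int(rng.integers(0, max(L - I, 0) + 1))
            seq[pos:pos] = [_BASES[int(b)] for b in rng.integers(0, 4, size=I)]
        else:  # substitution
            count = min(spec.substitution_count, L)
            positions = rng.choice(L, size=count, replace=False)
            for p, b in zip(positions, rng.integers(0, 4, size=count)):
                seq[int(p)] = _BASES[int(b)]
    return Read(read.identifier, "".join(seq))


def inject_dataset(rs: ReadSet, spec: ErrorSpec) -> ReadSet:
    """Inject errors independently into every read, order preserved;
    deterministic per ``spec.seed``."""
    if len(rs) == 0:
        raise SyntheticError("cannot inject errors into an empty read set")
    rng = np.random.default_rng(spec.seed)
    return ReadSet(
        [inject_errors(read, spec, rng) for read in rs], source_path=rs.source_path
    )


def write_truth(dataset: SimulatedDataset, path: str | Path) -> Path:
    """Write per-read truth as TSV: read_id, start (0-based), clean_sequence."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["read_id", "start", "clean_sequence"])
        for rid, rec in dataset.truth.items():
            writer.writerow([rid, rec.start, rec.sequence])
    return path


def load_truth(path: str | Path) -> dict[str, TruthRecord]:
    truth: dict[str, TruthRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["read_id", "start", "clean_sequence"]:
            raise SyntheticError(f"{path}: not a truth TSV")
        for rid, start, sequence in reader:
            truth[rid] = TruthRecord(int(start), sequence)
    return truth
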