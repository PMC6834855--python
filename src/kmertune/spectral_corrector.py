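"""Built-in k-spectrum error corrector and the adapter for external tools.

The k-spectrum paradigm: k-mers occurring at or above a frequency threshold
are *solid*, the rest *insolid* (untrusted); correction converts insolid
k-mers into solid ones with minimal edits.  The built-in corrector is
substitution-only and greedy — Illumina errors are overwhelmingly
substitutions — and exists so the tuning loop can be exercised hermetically:
its quality varies realistically with k, which is all the tuner requires.

At each read position covered exclusively by insolid k-mers, the three
alternative bases are evaluated and the substitution that maximizes the
number of solid k-mers covering the position is applied, only if it strictly
increases that number.  Read length and order are always preserved, and the
scan is deterministic.  No k-mer canonicalization is performed (forward
strand only, matching the simulator).

k-mers are packed 2 bits/base into int64 codes, so the per-read work is a
handful of vectorized numpy operations plus a short loop over candidate
positions.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .readset_io import Read, ReadSet, load_reads, write_reads

__all__ = [
    "SpectralError",
    "ExternalToolError",
    "SpectralParams",
    "ECToolSpec",
    "count_kmers",
    "correct_reads",
    "run_external_ec",
    "builtin_corrector",
    "external_corrector",
]

_BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
_DECODE = np.frombuffer(_BASES.encode(), dtype=np.uint8)


class SpectralError(ValueError):
    """Invalid corrector parameters or unusable input."""


class ExternalToolError(RuntimeError):
    """An external error-correction command failed."""


@dataclass
class SpectralParams:
    """Parameters of the built-in corrector: k-mer length, solid-count
    threshold, and the per-read cap on substitutions."""

    k: int
    solid_threshold: int = 2
    max_corrections_per_read: int = 4

    def __post_init__(self) -> None:
        if self.k < 1:
            raise SpectralError("k must be >= 1")
        if self.solid_threshold < 1:
            raise SpectralError("solid_threshold must be >= 1")
        if self.max_corrections_per_read < 0:
            raise SpectralError("max_corrections_per_read must be >= 0")


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a base string to int8 codes (A,C,G,T -> 0..3; anything else -> -1)."""
    return _CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]


def _powers(k: int) -> np.ndarray:
    if k > 31:
        raise SpectralError("k > 31 does not fit a packed 64-bit code")
    return 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)


def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed codes of all k-windows of a read plus a validity mask
    (windows containing non-ACGT characters are invalid)."""
    windows = sliding_window_view(codes, k).astype(np.int64)
    valid = (windows >= 0).all(axis=1)
    packed = windows @ _powers(k)
    packed[~valid] = -1
    return packed, valid


def _decode_kmer(code: int, k: int) -> str:
    digits = (code // 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)) % 4
    return _DECODE[digits].tobytes().decode()


def _gather_codes(rs: ReadSet, k: int) -> np.ndarray:
    chunks = []
    for read in rs:
        if len(read) < k:
            continue
        packed, valid = _window_codes(encode_sequence(read.sequence), k)
        if valid.any():
            chunks.append(packed[valid])
    if not chunks:
        raise SpectralError(f"k={k} exceeds every read length (or no ACGT windows)")
    return np.concatenate(chunks)


def count_kmers(rs: ReadSet, k: int) -> dict[str, int]:
    """Exact multiset counts of all length-k ACGT substrings of the reads.

    Windows containing N are skipped; no canonicalization is applied.
    """
    if k < 1:
        raise SpectralError("k must be >= 1")
    values, counts = np.unique(_gather_codes(rs, k), return_counts=True)
    return {_decode_kmer(int(v), k): int(c) for v, c in zip(values, counts)}


def _solid_spectrum(rs: ReadSet, k: int, threshold: int) -> np.ndarray:
    values, counts = np.unique(_gather_codes(rs, k), return_counts=True)
    return values[counts >= threshold]


def _is_solid(solid: np.ndarray, codes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(solid, codes)
    idx[idx == len(solid)] = 0 if len(solid) else 0
    if len(solid) == 0:
        return np.zeros(codes.shape, dtype=bool)
    return solid[idx] == codes


def _dilate(window_flags: np.ndarray, k: int, read_length: int) -> np.ndarray:
    """Per-position OR over the k-windows covering each position."""
    padded = np.zeros(read_length + k - 1, dtype=bool)
    padded[k - 1 : k - 1 + len(window_flags)] = window_flags
    return sliding_window_view(padded, k).any(axis=1)


def _fix_read(
    sequence: str,
    codes: np.ndarray,
    packed: np.ndarray,
    valid: np.ndarray,
    solid_mask: np.ndarray,
    candidates: np.ndarray,
    k: int,
    solid_set: set[int],
    max_corrections: int,
    powers: np.ndarray,
) -> str:
    """Greedy left-to-right substitution pass over one read's candidate
    positions.  Works on plain Python lists and a set of solid codes: the
    spans touched per candidate are tiny, where list indexing and set
    membership beat array-call overhead by an order of magnitude."""
    L = len(sequence)
    seq = list(sequence)
    codes_l = codes.tolist()
    packed_l = packed.tolist()
    valid_l = valid.tolist()
    solid_l = solid_mask.tolist()
    pw = powers.tolist()  # pw[j] == 4**(k-1-j): weight of offset j inside a window
    changes = 0
    n_windows = L - k + 1
    for p in candidates.tolist():
        lo = p - k + 1 if p >= k else 0
        hi = p if p < n_windows else n_windows - 1
        if True in solid_l[lo : hi + 1]:
            continue  # an earlier fix already made a covering window solid
        base = codes_l[p]
        if base < 0:
            continue  # N positions are left alone
        best_alt, best_count = -1, 0
        for alt in range(4):
            if alt == base:
                continue
            delta = alt - base
            count = 0
            for w in range(lo, hi + 1):
                if valid_l[w] and packed_l[w] + delta * pw[p - w] in solid_set:
                    count += 1
            if count > best_count:
                best_count, best_alt = count, alt
        if best_count > 0:
            delta = best_alt - base
            for w in range(lo, hi + 1):
                code = packed_l[w] + delta * pw[p - w]
                packed_l[w] = code
                solid_l[w] = valid_l[w] and code in solid_set
            codes_l[p] = best_alt
            seq[p] = _BASES[best_alt]
            changes += 1
            if changes >= max_corrections:
                break
    return "".join(seq)


def _packed_matrix(codes_mat: np.ndarray, k: int, powers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Packed window codes and validity for a (reads x length) code matrix,
    built with a rolling update so no (N, W, k) intermediate is materialized."""
    c = codes_mat.astype(np.int64)
    n_reads, L = c.shape
    W = L - k + 1
    packed = np.empty((n_reads, W), dtype=np.int64)
    packed[:, 0] = c[:, :k] @ powers
    top = np.int64(4) ** (k - 1)
    for j in range(1, W):
        packed[:, j] = (packed[:, j - 1] - c[:, j - 1] * top) * 4 + c[:, j + k - 1]
    neg = np.cumsum(np.pad(c < 0, ((0, 0), (1, 0))), axis=1)
    valid = (neg[:, k:] - neg[:, :-k]) == 0
    packed[~valid] = -1
    return packed, valid


def _dilate_matrix(window_flags: np.ndarray, k: int, read_length: int) -> np.ndarray:
    """Row-wise per-position OR over the k-windows covering each position."""
    n_reads, W = window_flags.shape
    padded = np.zeros((n_reads, read_length + k - 1), dtype=bool)
    padded[:, k - 1 : k - 1 + W] = window_flags
    return sliding_window_view(padded, k, axis=1).any(axis=2)


def correct_reads(rs: ReadSet, params: SpectralParams) -> ReadSet:
    """Correct `rs` with the built-in k-spectrum corrector.

    The spectrum (and hence solidity) is computed from `rs` itself.  Reads
    that cannot be improved pass through unchanged; output length and order
    always match the input.
    """
    k = params.k
    powers = _powers(k)
    lengths = {len(r) for r in rs}
    if not lengths or max(lengths) < k:
        raise SpectralError(f"k={k} exceeds every read length")
    if len(lengths) == 1:
        # uniform read length: one vectorized pass over the whole set
        L = lengths.pop()
        flat = encode_sequence("".join(r.sequence for r in rs))
        codes_mat = flat.reshape(len(rs), L)
        packed, valid = _packed_matrix(codes_mat, k, powers)
        if not valid.any():
            raise SpectralError(f"no ACGT window of length k={k} in the reads")
        values, counts = np.unique(packed[valid], return_counts=True)
        solid = values[counts >= params.solid_threshold]
        solid_set = set(solid.tolist())
        solid_mask = valid & _is_solid(solid, packed)
        candidate_mask = _dilate_matrix(valid, k, L) & ~_dilate_matrix(solid_mask, k, L)
        rows = np.flatnonzero(candidate_mask.any(axis=1))
        corrected = list(rs.reads)
        if params.max_corrections_per_read > 0:
            for i in rows:
                read = rs[int(i)]
                seq = _fix_read(
                    read.sequence,
                    codes_mat[i],
                    packed[i],
                    valid[i],
                    solid_mask[i],
                    np.flatnonzero(candidate_mask[i]),
                    k,
                    solid_set,
                    params.max_corrections_per_read,
                    powers,
                )
                if seq != read.sequence:
                    corrected[int(i)] = Read(read.identifier, seq, read.qualities)
        return ReadSet(corrected, source_path=rs.source_path)
    # mixed read lengths: per-read windows
    solid = _solid_spectrum(rs, k, params.solid_threshold)
    solid_set = set(solid.tolist())
    corrected = []
    for read in rs:
        seq = read.sequence
        if len(read) >= k and params.max_corrections_per_read > 0:
            codes = encode_sequence(seq).copy()
            packed, valid = _window_codes(codes, k)
            solid_mask = valid & _is_solid(solid, packed)
            if not solid_mask.all():
                cand = np.flatnonzero(
                    _dilate(valid, k, len(seq)) & ~_dilate(solid_mask, k, len(seq))
                )
                if cand.size:
                    seq = _fix_read(
                        seq, codes, packed, valid, solid_mask, cand, k, solid_set,
                        params.max_corrections_per_read, powers,
                    )
        corrected.append(Read(read.identifier, seq, read.qualities))
    return ReadSet(corrected, source_path=rs.source_path)


@dataclass
class ECToolSpec:
    """Adapter contract for an external error-correction executable.

    ``command_template`` must contain the ``{input}``, ``{output}`` and
    ``{value}`` placeholders; ``parameter_grid`` is either an explicit ordered
    value list (e.g. genome lengths for a genome-length-tuned tool) or an
    arithmetic ``range``-like sequence of parameter values.
    """

    name: str
    command_template: str
    parameter_name: str = "k"
    parameter_grid: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for placeholder in ("{input}", "{output}", "{value}"):
            if placeholder not in self.command_template:
                raise SpectralError(
                    f"command_template for {self.name!r} lacks {placeholder}"
                )
        self.parameter_grid = list(self.parameter_grid)
        if not self.parameter_grid:
            raise SpectralError(f"parameter_grid for {self.name!r} is empty")


def run_external_ec(
    spec: ECToolSpec,
    rs: ReadSet,
    value,
    workdir: str | Path,
    timeout: float | None = None,
) -> ReadSet:
    """Run an external corrector at one parameter value.

    Writes `rs` to the input placeholder path, substitutes `value` into the
    template, invokes the command through the shell, captures stdout/stderr
    to a log file in `workdir`, and loads the output placeholder path.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    in_path = workdir / f"{spec.name}_input.fastq"
    out_path = workdir / f"{spec.name}_{spec.parameter_name}{value}_output.fastq"
    log_path = workdir / f"{spec.name}_{spec.parameter_name}{value}.log"
    write_reads(rs, in_path, "fastq")
    command = spec.command_template.format(input=in_path, output=out_path, value=value)
    try:
        proc = subprocess.run(
            command, shell=True, capture_output=True, text=True, timeout=timeout
        )
    except subprocess.TimeoutExpired as exc:
        raise ExternalToolError(
            f"{spec.name} timed out after {timeout}s: {command}"
        ) from exc
    log_path.write_text(
        f"$ {command}\n--- stdout ---\n{proc.stdout}\n--- stderr ---\n{proc.stderr}\n"
    )
    if proc.returncode != 0:
        raise ExternalToolError(
            f"{spec.name} exited {proc.returncode}; stderr: {proc.stderr.strip()}"
        )
    if not out_path.exists() or out_path.stat().st_size == 0:
        raise ExternalToolError(f"{spec.name} produced no output at {out_path}")
    return load_reads(out_path, "fastq")


def builtin_corrector(
    solid_threshold: int = 2, max_corrections_per_read: int = 4
) -> Callable[[ReadSet, int], ReadSet]:
    """A corrector callable ``(reads, k) -> corrected`` over the built-in engine."""

    def ec(rs: ReadSet, value) -> ReadSet:
        params = SpectralParams(
            k=int(value),
            solid_threshold=solid_threshold,
            max_corrections_per_read=max_corrections_per_read,
        )
        return correct_reads(rs, params)

    return ec


def external_corrector(
    spec: ECToolSpec, workdir: str | Path, timeout: float | None = None
) -> Callable[[ReadSet, int], ReadSet]:
    """A corrector callable over :func:`run_external_ec` for the tuner."""

    def ec(rs: ReadSet, value) -> ReadSet:
        return run_external_ec(spec, rs, value, workdir, timeout=timeout)

    return ec
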