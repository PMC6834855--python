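"""Reading, writing and validation of short-read datasets.

FASTQ (4-line records) and FASTA are supported, gzip-compressed variants
transparently.  Reads are uppercased on load and restricted to the alphabet
``{A, C, G, T, N}``; anything else is rejected.  Multi-line FASTA is accepted
on input, single-line FASTA is emitted on output.  No reverse-complement
canonicalization is performed anywhere: reads are used exactly as given.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "ReadSet",
    "ReadSetError",
    "load_reads",
    "write_reads",
]

_ALLOWED = frozenset("ACGTN")
_FASTA_EXTS = {".fa", ".fasta", ".fna"}
_FASTQ_EXTS = {".fq", ".fastq"}

#: Quality character used when quality-less reads are written as FASTQ
#: (Phred 40; downstream correctors require a quality line, the value is inert).
DEFAULT_QUALITY_CHAR = "I"


class ReadSetError(ValueError):
    """Malformed read file or invalid read data."""


@dataclass
class Read:
    """A single sequencing read.

    Parameters
    ----------
    identifier
        Record name (FASTA/FASTQ header without the leading ``>``/``@``).
    sequence
        Base string over ``{A, C, G, T, N}``; lowercase input is uppercased.
    qualities
        Optional per-base Phred+33 quality string, same length as `sequence`.
    """

    identifier: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ReadSetError(f"read {self.identifier!r}: empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ReadSetError(
                f"read {self.identifier!r}: invalid characters {sorted(bad)!r}"
            )
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ReadSetError(
                f"read {self.identifier!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    """An ordered collection of reads (the uncorrected set and its corrections)."""

    reads: list[Read] = field(default_factory=list)
    source_path: str | None = None
    declared_read_length: int | None = None

    def __post_init__(self) -> None:
        if self.declared_read_length is None and self.reads:
            self.declared_read_length = self.modal_read_length()

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __getitem__(self, i):
        return self.reads[i]

    def modal_read_length(self) -> int:
        """Most common read length in the set (ties broken by first occurrence)."""
        if not self.reads:
            raise ReadSetError("empty read set has no modal length")
        return Counter(len(r) for r in self.reads).most_common(1)[0][0]

    def total_bases(self) -> int:
        return sum(len(r) for r in self.reads)


def _open_text(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _detect_format(path: Path, fmt: str) -> str:
    if fmt in ("fastq", "fasta"):
        return fmt
    if fmt != "auto":
        raise ReadSetError(f"unknown format {fmt!r} (expected fastq, fasta or auto)")
    suffixes = path.suffixes
    ext = suffixes[-2] if suffixes and suffixes[-1] == ".gz" and len(suffixes) > 1 else path.suffix
    if ext in _FASTQ_EXTS:
        return "fastq"
    if ext in _FASTA_EXTS:
        return "fasta"
    raise ReadSetError(f"cannot infer read format from extension of {path}")


def load_reads(path: str | Path, format: str = "auto") -> ReadSet:
    """Load a FASTA/FASTQ file (optionally gzipped) into a :class:`ReadSet`.

    Input order is preserved, sequences are uppercased, and characters outside
    ``{A, C, G, T, N}`` are rejected.  Raises :class:`ReadSetError` for a
    missing file, a malformed record (e.g. quality/sequence length mismatch)
    or an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise ReadSetError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    reads: list[Read] = []
    try:
        with _open_text(path) as handle:
            for record in SeqIO.parse(handle, fmt):
                quals = None
                if "phred_quality" in record.letter_annotations:
                    quals = "".join(
                        chr(q + 33) for q in record.letter_annotations["phred_quality"]
                    )
                identifier = record.description or record.id
                reads.append(Read(identifier, str(record.seq), quals))
    except ReadSetError:
        raise
    except ValueError as exc:  # Biopython signals malformed records this way
        raise ReadSetError(f"malformed {fmt} record in {path}: {exc}") from exc
    if not reads:
        raise ReadSetError(f"no records found in {path}")
    return ReadSet(reads, source_path=str(path))


def write_reads(rs: ReadSet, path: str | Path, format: str = "fastq") -> Path:
    """Write a :class:`ReadSet` as FASTQ or single-line FASTA (gzip by extension).

    Quality-less reads written as FASTQ receive a constant quality line of
    :data:`DEFAULT_QUALITY_CHAR`.  Round trip through :func:`load_reads`
    reproduces identifiers and sequences exactly.
    """
    path = Path(path)
    if len(rs) == 0:
        raise ReadSetError("refusing to write an empty read set")
    if format not in ("fastq", "fasta"):
        raise ReadSetError(f"unknown output format {format!r}")
    records = []
    for read in rs:
        rec = SeqRecord(Seq(read.sequence), id=read.identifier, description="")
        if format == "fastq":
            quals = read.qualities or DEFAULT_QUALITY_CHAR * len(read)
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in quals]
        records.append(rec)
    seqio_fmt = "fastq" if format == "fastq" else "fasta-2line"
    try:
        with _open_text(path, "wt") as handle:
            SeqIO.write(records, handle, seqio_fmt)
    except OSError as exc:
        raise ReadSetError(f"cannot write {path}: {exc}") from exc
    return path
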