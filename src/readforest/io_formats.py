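"""Reading and writing fixed-length DNA read multisets (FASTA/FASTQ).

The compressor is defined on a multiset of reads of one fixed length L over
{A, C, G, T, N}.  Identifiers and quality strings are discarded at parse time:
only the sequences are compressed, and decompression emits FASTA with
generated identifiers.  Record order of the input file is preserved in the
returned :class:`ReadSet` (the *compressed* representation, however, is a
multiset — decompressed order is unspecified).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Union

from Bio import SeqIO

from .exceptions import (
    AlphabetError,
    EmptyInputError,
    FixedLengthError,
    ParseError,
)

_ALPHABET = frozenset("ACGTN")

PathType = Union[str, PathLike]


@dataclass
class ReadSet:
    """An ordered multiset of fixed-length reads.

    Attributes
    ----------
    reads:
        Uppercase DNA strings over {A, C, G, T, N}, all of length ``L``.
    L:
        Common read length in bases.
    """

    reads: list[str] = field(default_factory=list)
    L: int = 0

    @property
    def N_total(self) -> int:
        """Total read count, duplicates included."""
        return len(self.reads)

    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "ReadSet":
        """Validate and wrap an iterable of sequences."""
        reads: list[str] = []
        L = 0
        for i, seq in enumerate(seqs):
            seq = seq.upper()
            if set(seq) - _ALPHABET:
                bad = sorted(set(seq) - _ALPHABET)
                raise AlphabetError(
                    f"read {i + 1}: characters {bad} outside A/C/G/T/N"
                )
            if not reads:
                L = len(seq)
            elif len(seq) != L:
                raise FixedLengthError(
                    f"read {i + 1} has length {len(seq)}, expected fixed L={L}"
                )
            reads.append(seq)
        return cls(reads=reads, L=L)


def _open_text(path: PathType) -> io.TextIOBase:
    """Open a possibly gzip-compressed text file transparently."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def _sniff_format(handle: io.TextIOBase) -> str:
    pos = handle.tell()
    first = ""
    for line in handle:
        if line.strip():
            first = line.lstrip()[0]
            break
    handle.seek(pos)
    if not first:
        raise EmptyInputError("no sequence records found")
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError(
        "cannot determine format: first record starts with "
        f"{first!r}, expected '>' (FASTA) or '@' (FASTQ)"
    )


def read_fastx(path: PathType, format: str = "auto") -> ReadSet:
    """Parse a FASTA or FASTQ file into a :class:`ReadSet`.

    Sequences are uppercased; identifiers and qualities are discarded; file
    order is preserved.  Gzip-compressed input is handled transparently.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"fasta"``, ``"fastq"``, or ``"auto"`` (sniff from the first record).

    Raises
    ------
    ParseError, FixedLengthError, AlphabetError, EmptyInputError
    """
    if format not in ("auto", "fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    with _open_text(path) as handle:
        fmt = _sniff_format(handle) if format == "auto" else format
        seqs: list[str] = []
        record_no = 0
        try:
            for record in SeqIO.parse(handle, fmt):
                record_no += 1
                seqs.append(str(record.seq))
        except ValueError as exc:
            # Biopython reports malformed records as ValueError; FASTQ records
            # occupy exactly 4 lines, so the failing line is recoverable.
            line = record_no * 4 + 1 if fmt == "fastq" else None
            where = f"near line {line}" if line else f"after record {record_no}"
            raise ParseError(f"{path}: malformed {fmt} record {where}: {exc}") from exc
    if not seqs:
        raise EmptyInputError(f"{path}: no sequence records found")
    try:
        return ReadSet.from_sequences(seqs)
    except (AlphabetError, FixedLengthError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_fastx(rs: ReadSet, path: PathType) -> int:
    """Write a ReadSet as FASTA with sequential identifiers ``read_1``…

    Returns the number of records written.  Note that a decompressed ReadSet
    is a multiset: its order need not match the originally compressed file.
    """
    with open(path, "w") as out:
        for i, seq in enumerate(rs.reads, start=1):
            out.write(f">read_{i}\n{seq}\n")
    return rs.N_total
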