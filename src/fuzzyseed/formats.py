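"""FASTA/FASTQ input and PAF output/parsing.

Sequence parsing is delegated to Biopython's streaming parsers behind a
line-counting handle so that malformed records are reported with a line
number.  All coordinates everywhere in the package are 0-based half-open;
reverse-strand PAF records report target coordinates on the forward strand
of the target (standard PAF convention).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import IO, Iterator, Optional, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed input; carries the (approximate) line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        where = f" (near line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence; ``name`` is the first whitespace-delimited header token."""

    name: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"quality length {len(self.qual)} != sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


class _CountingHandle:
    """Text-stream wrapper that remembers how many lines were consumed."""

    def __init__(self, handle: IO[str]):
        self._handle = handle
        self.line = 0

    def __iter__(self):
        return self

    def __next__(self) -> str:
        line = next(self._handle)
        self.line += 1
        return line

    def readline(self) -> str:
        line = self._handle.readline()
        if line:
            self.line += 1
        return line

    def read(self, size: int = -1) -> str:
        # Biopython probes the stream type with read(0); real reads would
        # bypass line counting, so only the probe is supported.
        if size == 0:
            return ""
        raise io.UnsupportedOperation("line-based access only")


def _open_text(path_or_stream) -> IO[str]:
    if hasattr(path_or_stream, "read"):
        return path_or_stream
    raw = open(path_or_stream, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(raw), encoding="ascii")
    return io.TextIOWrapper(raw, encoding="ascii")


def read_sequences(path_or_stream: Union[str, IO[str]]) -> Iterator[SeqRecord]:
    """Stream records from FASTA or FASTQ, plain or gzip, auto-detected.

    Yields :class:`SeqRecord` in file order; multi-line FASTA is joined and
    sequence case is preserved.  Malformed records (FASTQ length mismatch,
    empty header) raise :class:`ParseError` with a line number.
    """
    handle = _open_text(path_or_stream)
    first = handle.read(1)
    if first == "":
        return
    rest = handle.read()
    counting = _CountingHandle(io.StringIO(first + rest))
    if first == ">":
        parser = SimpleFastaParser(counting)
        is_fastq = False
    elif first == "@":
        parser = FastqGeneralIterator(counting)
        is_fastq = True
    else:
        raise ParseError(f"unrecognized leading character {first!r}", line=1)
    try:
        for fields in parser:
            if is_fastq:
                title, seq, qual = fields
            else:
                title, seq = fields
                qual = None
            name = title.split()[0] if title.split() else ""
            if not name:
                raise ParseError("empty sequence header", line=counting.line)
            try:
                yield SeqRecord(name=name, seq=seq, qual=qual)
            except ValueError as exc:
                raise ParseError(str(exc), line=counting.line) from exc
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(str(exc), line=counting.line) from exc


PAF_MISSING_MAPQ = 255  # missing-quality sentinel per the PAF convention


@dataclass(frozen=True)
class PafRecord:
    """The 12 mandatory PAF columns plus optional typed tags."""

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    residue_matches: int
    block_len: int
    mapq: int
    tags: tuple = field(default_factory=tuple)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for side, start, end, length in (
            ("query", self.query_start, self.query_end, self.query_len),
            ("target", self.target_start, self.target_end, self.target_len),
        ):
            if not 0 <= start < end <= length:
                raise ValueError(
                    f"{side} interval [{start}, {end}) invalid for length {length}"
                )
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"mapq {self.mapq} outside [0, 255]")

    def to_line(self) -> str:
        cols = [
            self.query_name, str(self.query_len), str(self.query_start),
            str(self.query_end), self.strand, self.target_name,
            str(self.target_len), str(self.target_start), str(self.target_end),
            str(self.residue_matches), str(self.block_len), str(self.mapq),
        ]
        for key, typ, value in self.tags:
            cols.append(f"{key}:{typ}:{value}")
        return "\t".join(cols)


_TAG_PARSERS = {"i": int, "f": float, "A": str, "Z": str}


def write_paf(records, stream: IO[str]) -> int:
    """Write records as PAF lines; returns the line count.

    Every record is validated before any output is produced for it, so an
    invalid record (e.g. an empty half-open interval) is rejected on write.
    """
    count = 0
    for rec in records:
        rec.validate()
        stream.write(rec.to_line() + "\n")
        count += 1
    return count


def parse_paf(stream: Union[str, IO[str]]) -> Iterator[PafRecord]:
    """Parse PAF lines into :class:`PafRecord`; round trips :func:`write_paf`."""
    handle = _open_text(stream)
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ParseError(
                f"PAF line has {len(cols)} columns, expected >= 12", line=lineno
            )
        try:
            tags = []
            for col in cols[12:]:
                key, typ, value = col.split(":", 2)
                tags.append((key, typ, _TAG_PARSERS.get(typ, str)(value)))
            rec = PafRecord(
                query_name=cols[0], query_len=int(cols[1]),
                query_start=int(cols[2]), query_end=int(cols[3]),
                strand=cols[4], target_name=cols[5],
                target_len=int(cols[6]), target_start=int(cols[7]),
                target_end=int(cols[8]), residue_matches=int(cols[9]),
                block_len=int(cols[10]), mapq=int(cols[11]),
                tags=tuple(tags),
            )
            rec.validate()
        except ValueError as exc:
            raise ParseError(f"malformed PAF line: {exc}", line=lineno) from exc
        yield rec
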