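"""Streaming FASTA / FASTQ / QUAL parsers and writers.

All three are record-streaming: memory is bounded by the largest single
record, never by file size.  FASTQ is read and written strictly as
four-line records with Phred+33 qualities (the Sanger convention); legacy
Phred+64 input can be decoded by passing ``offset=64``.
"""

from __future__ import annotations

from typing import IO, Iterable, Iterator

from ..errors import ParseError
from .records import SeqRecord, phred_decode, phred_encode


def _split_header(line: str) -> tuple[str, str]:
    parts = line.split(None, 1)
    if not parts:
        raise ParseError("empty header line")
    description = parts[1].rstrip() if len(parts) == 2 else ""
    return parts[0], description


def parse_fastq(
    source: IO[str], metadata: dict | None = None, offset: int = 33
) -> Iterator[SeqRecord]:
    """Yield one :class:`SeqRecord` per four-line FASTQ record."""
    lineno = 0
    while True:
        header = source.readline()
        if not header:
            return
        lineno += 1
        if not header.strip():
            continue
        if not header.startswith("@"):
            raise ParseError(f"expected '@' header, got {header.strip()!r}", line=lineno)
        seq = source.readline()
        plus = source.readline()
        qual = source.readline()
        if not qual:
            raise ParseError("truncated FASTQ record", line=lineno)
        lineno += 3
        if not plus.startswith("+"):
            raise ParseError(
                f"expected '+' separator, got {plus.strip()!r}", line=lineno - 1
            )
        rec_id, description = _split_header(header[1:])
        sequence = seq.strip()
        quality = qual.rstrip("\n")
        if len(quality) != len(sequence):
            raise ParseError(
                f"record {rec_id!r}: quality length {len(quality)} != "
                f"sequence length {len(sequence)}",
                line=lineno,
            )
        yield SeqRecord(
            id=rec_id,
            description=description,
            sequence=sequence,
            quality=phred_decode(quality, offset=offset),
        ).validate()


def parse_fasta(source: IO[str], metadata: dict | None = None) -> Iterator[SeqRecord]:
    """Yield :class:`SeqRecord` objects from FASTA; sequences may span lines."""
    rec_id: str | None = None
    description = ""
    chunks: list[str] = []
    lineno = 0
    for line in source:
        lineno += 1
        if line.startswith(">"):
            if rec_id is not None:
                yield SeqRecord(rec_id, description, "".join(chunks)).validate()
            try:
                rec_id, description = _split_header(line[1:])
            except ParseError as exc:
                raise ParseError("empty FASTA header", line=lineno) from exc
            chunks = []
        elif line.strip():
            if rec_id is None:
                raise ParseError("sequence data before the first '>' header", line=lineno)
            chunks.append(line.strip())
    if rec_id is not None:
        yield SeqRecord(rec_id, description, "".join(chunks)).validate()


def parse_qual(source: IO[str], metadata: dict | None = None) -> Iterator[SeqRecord]:
    """Yield quality-only records ('>' headers, whitespace-separated scores)."""

    def finish(rec_id: str, description: str, tokens: list[str], lineno: int) -> SeqRecord:
        try:
            quality = [int(tok) for tok in tokens]
        except ValueError as exc:
            raise ParseError(f"non-integer quality score in record {rec_id!r}", line=lineno) from exc
        return SeqRecord(rec_id, description, "", quality)

    rec_id: str | None = None
    description = ""
    tokens: list[str] = []
    lineno = 0
    for line in source:
        lineno += 1
        if line.startswith(">"):
            if rec_id is not None:
                yield finish(rec_id, description, tokens, lineno)
            rec_id, description = _split_header(line[1:])
            tokens = []
        elif line.strip():
            if rec_id is None:
                raise ParseError("scores before the first '>' header", line=lineno)
            tokens.extend(line.split())
    if rec_id is not None:
        yield finish(rec_id, description, tokens, lineno)


def wrap(text: str, width: int) -> Iterator[str]:
    """Slice ``text`` into lines of at most ``width`` characters (0 = no wrap)."""
    if width <= 0 or len(text) <= width:
        yield text
        return
    for i in range(0, len(text), width):
        yield text[i : i + width]


def write_fasta(records: Iterable[SeqRecord], sink: IO[str], wrap_width: int = 80) -> int:
    """Write FASTA, wrapping sequence lines at ``wrap_width`` columns."""
    count = 0
    for rec in records:
        sink.write(f">{rec.header}\n")
        for line in wrap(rec.sequence, wrap_width):
            sink.write(line + "\n")
        count += 1
    return count


def write_fastq(records: Iterable[SeqRecord], sink: IO[str], offset: int = 33) -> int:
    count = 0
    for rec in records:
        if rec.quality is None:
            raise ParseError(f"record {rec.id!r} has no quality scores; cannot write FASTQ")
        rec.validate()
        sink.write(f"@{rec.header}\n{rec.sequence}\n+\n{phred_encode(rec.quality, offset)}\n")
        count += 1
    return count


def write_qual(records: Iterable[SeqRecord], sink: IO[str], per_line: int = 20) -> int:
    """Write QUAL: '>' headers and space-separated scores, ``per_line`` per row."""
    count = 0
    for rec in records:
        if rec.quality is None:
            raise ParseError(f"record {rec.id!r} has no quality scores; cannot write QUAL")
        sink.write(f">{rec.header}\n")
        scores = rec.quality
        if not scores:
            sink.write("\n")
        for i in range(0, len(scores), per_line):
            sink.write(" ".join(str(q) for q in scores[i : i + per_line]) + "\n")
        count += 1
    return count
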