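"""Tab-delimited genomic formats: GFF3, VCF and SAM parsing, BED writing.

All three parsers stream line by line; header and comment lines (``#``
directives in GFF3/VCF, ``@`` lines in SAM) are collected into the
caller-supplied metadata mapping instead of being yielded as records.
"""

from __future__ import annotations

from typing import IO, Iterable, Iterator
from urllib.parse import unquote

from ..errors import ParseError
from .records import Gff3Feature, Interval, SamRecord, VcfRecord


def parse_gff3_attributes(text: str) -> dict[str, str]:
    """Split ``key=value;key=value`` attribute text, percent-decoding values."""
    attributes: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attributes[unquote(key.strip())] = unquote(value.strip())
    return attributes


def parse_gff3(source: IO[str], metadata: dict | None = None) -> Iterator[Gff3Feature]:
    lineno = 0
    for line in source:
        lineno += 1
        if line.startswith("#"):
            if metadata is not None:
                metadata.setdefault("headers", []).append(line.rstrip("\n"))
            continue
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise ParseError(
                f"GFF3 row has {len(fields)} columns, expected 9", line=lineno
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise ParseError(
                f"non-integer GFF3 coordinates {fields[3]!r}..{fields[4]!r}", line=lineno
            ) from None
        yield Gff3Feature(
            seqid=fields[0],
            source=fields[1],
            type=fields[2],
            start=start,
            end=end,
            score=fields[5],
            strand=fields[6],
            phase=fields[7],
            attributes=parse_gff3_attributes(fields[8]),
            line=lineno,
        )


def parse_vcf(source: IO[str], metadata: dict | None = None) -> Iterator[VcfRecord]:
    lineno = 0
    for line in source:
        lineno += 1
        if line.startswith("#"):
            if metadata is not None:
                metadata.setdefault("headers", []).append(line.rstrip("\n"))
            continue
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 8:
            raise ParseError(
                f"VCF row has {len(fields)} columns, expected >= 8", line=lineno
            )
        try:
            pos = int(fields[1])
        except ValueError:
            raise ParseError(f"non-integer VCF POS {fields[1]!r}", line=lineno) from None
        yield VcfRecord(
            chrom=fields[0],
            pos=pos,
            id=fields[2],
            ref=fields[3],
            alt=fields[4],
            qual=fields[5],
            filter=fields[6],
            info=fields[7],
            rest=fields[8:],
            line=lineno,
        )


def parse_sam(source: IO[str], metadata: dict | None = None) -> Iterator[SamRecord]:
    lineno = 0
    for line in source:
        lineno += 1
        if line.startswith("@"):
            if metadata is not None:
                metadata.setdefault("headers", []).append(line.rstrip("\n"))
            continue
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise ParseError(
                f"SAM row has {len(fields)} columns, expected >= 11", line=lineno
            )
        try:
            flag = int(fields[1])
            pos = int(fields[3])
            mapq = int(fields[4])
            pnext = int(fields[7])
            tlen = int(fields[8])
        except ValueError:
            raise ParseError("non-integer numeric SAM column", line=lineno) from None
        try:
            yield SamRecord(
                qname=fields[0],
                flag=flag,
                rname=fields[2],
                pos=pos,
                mapq=mapq,
                cigar=fields[5],
                rnext=fields[6],
                pnext=pnext,
                tlen=tlen,
                seq=fields[9],
                qual=fields[10],
                tags=fields[11:],
            ).validate()
        except ParseError as exc:
            raise ParseError(str(exc), line=lineno) from None


def write_bed(intervals: Iterable[Interval], sink: IO[str]) -> int:
    """Write 6-column BED: chrom, start, end, name, score, strand."""
    count = 0
    for iv in intervals:
        iv.validate()
        sink.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score}\t{iv.strand}\n")
        count += 1
    return count
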