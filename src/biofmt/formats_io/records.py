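"""In-memory record types and the record-level transforms conversions use.

Coordinate conventions: :class:`Interval` is always 0-based half-open (the
BED convention); GFF3 and VCF rows carry their native 1-based coordinates
and are shifted only when converted to an :class:`Interval`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import CoordinateError, EncodingError, ParseError

#: highest Phred score representable in the printable Phred+33 range
MAX_PHRED = 93

SECONDARY_FLAG = 0x100
SUPPLEMENTARY_FLAG = 0x800
REVERSE_FLAG = 0x10


@dataclass
class SeqRecord:
    """A sequence with optional per-base Phred qualities.

    QUAL-format records carry qualities with an empty sequence; everywhere
    else a present ``quality`` list has the same length as ``sequence``
    (the FASTQ parser and writer enforce this).
    """

    id: str
    description: str = ""
    sequence: str = ""
    quality: list[int] | None = None

    def validate(self) -> "SeqRecord":
        if not self.id or any(c.isspace() for c in self.id):
            raise ParseError(f"record id must be a non-empty token: {self.id!r}")
        if self.quality is not None and self.sequence:
            if len(self.quality) != len(self.sequence):
                raise ParseError(
                    f"record {self.id!r}: quality length {len(self.quality)} "
                    f"!= sequence length {len(self.sequence)}"
                )
            bad = [q for q in self.quality if not 0 <= q <= MAX_PHRED]
            if bad:
                raise ParseError(
                    f"record {self.id!r}: Phred scores outside [0, {MAX_PHRED}]: {bad[:5]}"
                )
        return self

    @property
    def header(self) -> str:
        """Header text after the marker character: id plus description."""
        return f"{self.id} {self.description}" if self.description else self.id


@dataclass
class Alignment:
    """A multiple sequence alignment: equal-length gapped records."""

    records: list[SeqRecord]
    metadata: dict = field(default_factory=dict)

    def validate(self) -> "Alignment":
        if not self.records:
            raise ParseError("alignment must contain at least one record")
        length = len(self.records[0].sequence)
        for rec in self.records:
            if len(rec.sequence) != length:
                raise ParseError(
                    f"alignment record {rec.id!r} has length {len(rec.sequence)}, "
                    f"expected {length}"
                )
        ids = [rec.id for rec in self.records]
        if len(set(ids)) != len(ids):
            raise ParseError("alignment record ids are not unique")
        return self

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class TreeDocument:
    """One or more phylogenetic trees as (label, newick) pairs.

    ``translate`` maps shorthand tokens to taxon names (the NEXUS
    ``Translate`` table); it is applied when writing plain newick.
    """

    trees: list[tuple[str, str]]
    translate: dict[str, str] = field(default_factory=dict)

    def validate(self) -> "TreeDocument":
        for label, newick in self.trees:
            if newick.count("(") != newick.count(")"):
                raise ParseError(f"tree {label!r}: unbalanced parentheses")
            if not newick.rstrip().endswith(";"):
                raise ParseError(f"tree {label!r}: newick string must end with ';'")
        return self


@dataclass
class Interval:
    """A genomic interval, 0-based half-open, BED column order."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: object = "."
    strand: str = "."

    def validate(self) -> "Interval":
        if self.start < 0 or self.end <= self.start:
            raise CoordinateError(
                f"invalid half-open interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in {"+", "-", "."}:
            raise CoordinateError(f"invalid strand {self.strand!r}")
        return self


@dataclass
class Gff3Feature:
    """One GFF3 feature row with parsed attributes; coordinates 1-based inclusive."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, str]
    line: int = 0


@dataclass
class VcfRecord:
    """One VCF data row; POS is 1-based."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    qual: str
    filter: str
    info: str
    rest: list[str] = field(default_factory=list)
    line: int = 0


@dataclass
class SamRecord:
    """One SAM alignment line: the 11 mandatory columns plus verbatim tags."""

    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: str
    rnext: str
    pnext: int
    tlen: int
    seq: str
    qual: str
    tags: list[str] = field(default_factory=list)

    def validate(self) -> "SamRecord":
        if self.flag < 0:
            raise ParseError(f"record {self.qname!r}: negative FLAG {self.flag}")
        if self.seq != "*" and self.qual != "*" and len(self.seq) != len(self.qual):
            raise ParseError(
                f"record {self.qname!r}: SEQ length {len(self.seq)} != QUAL length {len(self.qual)}"
            )
        return self


# --------------------------------------------------------------------- phred

def phred_decode(qual: str, offset: int = 33) -> list[int]:
    """Decode a quality string into integer Phred scores."""
    scores = []
    for ch in qual:
        value = ord(ch) - offset
        if value < 0:
            raise EncodingError(
                f"character {ch!r} (ASCII {ord(ch)}) is below offset {offset}; "
                "wrong Phred offset?"
            )
        scores.append(value)
    return scores


def phred_encode(scores: list[int], offset: int = 33) -> str:
    """Encode integer Phred scores as a printable quality string."""
    for q in scores:
        if not 0 <= q <= MAX_PHRED:
            raise EncodingError(f"Phred score {q} outside the printable range [0, {MAX_PHRED}]")
    return "".join(chr(q + offset) for q in scores)


# ------------------------------------------------------------- complementing

_COMPLEMENT_PAIRS = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT = str.maketrans(
    {**_COMPLEMENT_PAIRS, **{k.lower(): v.lower() for k, v in _COMPLEMENT_PAIRS.items()}}
)


def reverse_complement(sequence: str) -> str:
    """Reverse-complement a nucleotide string.

    IUPAC ambiguity codes are complemented, case is preserved and unknown
    characters pass through unchanged.  On DNA alphabets the operation is
    an involution (U maps to A, so RNA strings do not round-trip).
    """
    return sequence.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------- transforms

def sam_to_seqrecord(record: SamRecord) -> SeqRecord | None:
    """Recover the original read from a SAM alignment line.

    Returns ``None`` for records without a stored sequence and for
    secondary (0x100) or supplementary (0x800) alignments, which would
    duplicate the read.  Reads aligned to the reverse strand (0x10) are
    reverse-complemented and their qualities reversed, restoring the
    orientation in which the read was sequenced.
    """
    if record.seq == "*":
        return None
    if record.flag & (SECONDARY_FLAG | SUPPLEMENTARY_FLAG):
        return None
    sequence = record.seq
    quality = None if record.qual == "*" else phred_decode(record.qual)
    if record.flag & REVERSE_FLAG:
        sequence = reverse_complement(sequence)
        if quality is not None:
            quality = quality[::-1]
    return SeqRecord(id=record.qname, sequence=sequence, quality=quality)


def gff3_to_interval(feature: Gff3Feature) -> Interval:
    """Shift a 1-based inclusive GFF3 feature to a 0-based half-open interval."""
    if feature.start < 1 or feature.end < feature.start:
        raise CoordinateError(
            f"invalid GFF3 coordinates {feature.start}..{feature.end} "
            f"(1-based inclusive required)"
        )
    strand = feature.strand if feature.strand in {"+", "-"} else "."
    return Interval(
        chrom=feature.seqid,
        start=feature.start - 1,
        end=feature.end,
        name=feature.attributes.get("ID", "."),
        score=feature.score if feature.score else ".",
        strand=strand,
    )


def variant_to_interval(record: VcfRecord) -> Interval:
    """Span of the reference allele as a 0-based half-open interval."""
    if record.pos < 1:
        raise CoordinateError(f"VCF POS must be >= 1, got {record.pos}")
    if not record.ref:
        raise CoordinateError(f"VCF record at {record.chrom}:{record.pos} has empty REF")
    return Interval(
        chrom=record.chrom,
        start=record.pos - 1,
        end=record.pos - 1 + len(record.ref),
        name=record.id if record.id else ".",
        score=record.qual if record.qual else ".",
        strand=".",
    )
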