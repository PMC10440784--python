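"""Native streaming parsers and writers for the supported text formats.

:func:`parse_records` and :func:`write_records` dispatch on a format name
from the registry; the per-format implementations live in the submodules
(:mod:`.sequences`, :mod:`.msa`, :mod:`.trees`, :mod:`.tabular`) and the
record types and transforms in :mod:`.records`.
"""

from __future__ import annotations

from typing import IO, Iterator

from ..errors import ParseError
from .records import (
    Alignment,
    Gff3Feature,
    Interval,
    SamRecord,
    SeqRecord,
    TreeDocument,
    VcfRecord,
    gff3_to_interval,
    phred_decode,
    phred_encode,
    reverse_complement,
    sam_to_seqrecord,
    variant_to_interval,
)
from .sequences import (
    parse_fasta,
    parse_fastq,
    parse_qual,
    write_fasta,
    write_fastq,
    write_qual,
)
from .msa import (
    parse_clustal,
    parse_phylip,
    parse_stockholm,
    truncate_phylip_names,
    write_clustal,
    write_phylip,
    write_stockholm,
)
from .trees import apply_translate, parse_newick, parse_nexus, write_newick, write_nexus
from .tabular import parse_gff3, parse_sam, parse_vcf, write_bed

PARSERS = {
    "fastq": parse_fastq,
    "fasta": parse_fasta,
    "qual": parse_qual,
    "clustal": parse_clustal,
    "phylip": parse_phylip,
    "stockholm": parse_stockholm,
    "newick": parse_newick,
    "nexus": parse_nexus,
    "gff3": parse_gff3,
    "vcf": parse_vcf,
    "sam": parse_sam,
}

WRITERS = {
    "fastq": write_fastq,
    "fasta": write_fasta,
    "qual": write_qual,
    "clustal": write_clustal,
    "phylip": write_phylip,
    "stockholm": write_stockholm,
    "newick": write_newick,
    "nexus": write_nexus,
    "bed": write_bed,
}


def parse_records(format: str, source: IO[str], metadata: dict | None = None) -> Iterator:
    """Lazily parse ``source`` as ``format``; header lines go to ``metadata``.

    Yields :class:`SeqRecord` for fastq/fasta/qual, :class:`Alignment` for
    the MSA formats, :class:`TreeDocument` for tree formats, and feature /
    variant / alignment rows for gff3 / vcf / sam.  Empty input yields no
    records; malformed records raise :class:`~biofmt.errors.ParseError`
    with a line number.
    """
    try:
        parser = PARSERS[format]
    except KeyError:
        raise ParseError(f"no parser registered for format {format!r}") from None
    return parser(source, metadata=metadata)


def write_records(format: str, records, sink: IO[str], **options) -> int:
    """Write ``records`` as ``format``; returns the record count written."""
    try:
        writer = WRITERS[format]
    except KeyError:
        raise ParseError(f"no writer registered for format {format!r}") from None
    return writer(records, sink, **options)


__all__ = [
    "Alignment",
    "Gff3Feature",
    "Interval",
    "SamRecord",
    "SeqRecord",
    "TreeDocument",
    "VcfRecord",
    "PARSERS",
    "WRITERS",
    "apply_translate",
    "gff3_to_interval",
    "parse_records",
    "phred_decode",
    "phred_encode",
    "reverse_complement",
    "sam_to_seqrecord",
    "truncate_phylip_names",
    "variant_to_interval",
    "write_records",
]
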