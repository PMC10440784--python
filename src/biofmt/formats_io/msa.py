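"""Multiple-sequence-alignment formats: CLUSTAL, PHYLIP, Stockholm.

Dialect choices (each a writer option where it matters):

* CLUSTAL output uses 60-column blocks and skips conservation lines on
  input.
* PHYLIP output is strict sequential with 10-character padded names; both
  sequential and interleaved layouts are accepted on input.  Names longer
  than 10 characters are truncated on write and a collision after
  truncation is an error.
* Stockholm output is single-block with the "# STOCKHOLM 1.0" header and
  "//" terminator; ``#=`` annotation lines are collected as metadata.
"""

from __future__ import annotations

from typing import IO, Iterator

from ..errors import ParseError
from .records import Alignment, SeqRecord

PHYLIP_NAME_WIDTH = 10


# ------------------------------------------------------------------- clustal

def parse_clustal(source: IO[str], metadata: dict | None = None) -> Iterator[Alignment]:
    """Parse a CLUSTAL alignment into a single :class:`Alignment`."""
    first = source.readline()
    if not first.upper().startswith("CLUSTAL"):
        raise ParseError(f"missing CLUSTAL header, got {first.strip()!r}", line=1)
    if metadata is not None:
        metadata["header"] = first.strip()
    order: list[str] = []
    chunks: dict[str, list[str]] = {}
    lineno = 1
    for line in source:
        lineno += 1
        if not line.strip():
            continue
        # conservation lines start with whitespace and hold only *:. marks
        if line[0].isspace():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"malformed CLUSTAL row {line.strip()!r}", line=lineno)
        name, seq = parts[0], parts[1]
        if name not in chunks:
            order.append(name)
            chunks[name] = []
        chunks[name].append(seq)
    if not order:
        raise ParseError("CLUSTAL file contains no sequences")
    records = [SeqRecord(name, "", "".join(chunks[name])) for name in order]
    yield Alignment(records).validate()


def write_clustal(alignments, sink: IO[str], block_width: int = 60) -> int:
    count = 0
    for alignment in _iter_alignments(alignments):
        alignment.validate()
        sink.write("CLUSTAL multiple sequence alignment\n\n")
        width = max(len(rec.id) for rec in alignment.records) + 3
        length = len(alignment.records[0].sequence)
        for start in range(0, max(length, 1), block_width):
            for rec in alignment.records:
                sink.write(f"{rec.id:<{width}}{rec.sequence[start:start + block_width]}\n")
            sink.write("\n")
        count += len(alignment.records)
    return count


# -------------------------------------------------------------------- phylip

def parse_phylip(source: IO[str], metadata: dict | None = None) -> Iterator[Alignment]:
    """Parse sequential or interleaved PHYLIP into one :class:`Alignment`."""
    header = source.readline()
    parts = header.split()
    if len(parts) != 2:
        raise ParseError(f"malformed PHYLIP header {header.strip()!r}", line=1)
    try:
        n_taxa, length = int(parts[0]), int(parts[1])
    except ValueError:
        raise ParseError(f"non-numeric PHYLIP header {header.strip()!r}", line=1) from None
    lines = [line.rstrip("\n") for line in source if line.strip()]
    if len(lines) < n_taxa:
        raise ParseError(f"PHYLIP declares {n_taxa} taxa but holds {len(lines)} rows")
    names: list[str] = []
    seqs: list[str] = []
    for row in lines[:n_taxa]:
        # strict 10-column name field; tolerate a whitespace-delimited name
        # shorter than 10 columns followed directly by sequence
        name = row[:PHYLIP_NAME_WIDTH].strip()
        body = row[PHYLIP_NAME_WIDTH:]
        if " " in name:
            name, _, rest = row.strip().partition(" ")
            body = rest
        names.append(name)
        seqs.append("".join(body.split()))
    remaining = lines[n_taxa:]
    if remaining:
        done = [len(s) >= length for s in seqs]
        interleaved = (
            not any(done)
            and len(set(len(s) for s in seqs)) == 1
            and len(remaining) % n_taxa == 0
        )
        if interleaved:
            for i, row in enumerate(remaining):
                seqs[i % n_taxa] += "".join(row.split())
        else:
            idx = 0
            for row in remaining:
                while idx < n_taxa and len(seqs[idx]) >= length:
                    idx += 1
                if idx == n_taxa:
                    raise ParseError("PHYLIP has more sequence data than declared")
                seqs[idx] += "".join(row.split())
    for name, seq in zip(names, seqs):
        if len(seq) != length:
            raise ParseError(
                f"PHYLIP taxon {name!r} has {len(seq)} sites, header declares {length}"
            )
    records = [SeqRecord(name, "", seq) for name, seq in zip(names, seqs)]
    yield Alignment(records).validate()


def truncate_phylip_names(ids: list[str]) -> list[str]:
    """Truncate ids to the 10-column PHYLIP name field, refusing collisions."""
    truncated = [i[:PHYLIP_NAME_WIDTH] for i in ids]
    seen: dict[str, str] = {}
    collisions = []
    for original, short in zip(ids, truncated):
        if short in seen and seen[short] != original:
            collisions.append((seen[short], original, short))
        seen.setdefault(short, original)
    if collisions:
        listing = "; ".join(f"{a!r} and {b!r} -> {s!r}" for a, b, s in collisions)
        raise ParseError(f"PHYLIP name truncation collides: {listing}")
    return truncated


def write_phylip(alignments, sink: IO[str]) -> int:
    """Write strict sequential PHYLIP: one padded-name row per taxon."""
    count = 0
    for alignment in _iter_alignments(alignments):
        alignment.validate()
        names = truncate_phylip_names([rec.id for rec in alignment.records])
        length = len(alignment.records[0].sequence)
        sink.write(f" {len(alignment.records)} {length}\n")
        for name, rec in zip(names, alignment.records):
            sink.write(f"{name:<{PHYLIP_NAME_WIDTH}}{rec.sequence}\n")
        count += len(alignment.records)
    return count


# ----------------------------------------------------------------- stockholm

def parse_stockholm(source: IO[str], metadata: dict | None = None) -> Iterator[Alignment]:
    first = source.readline()
    if not first.startswith("# STOCKHOLM"):
        raise ParseError(f"missing '# STOCKHOLM' header, got {first.strip()!r}", line=1)
    order: list[str] = []
    chunks: dict[str, list[str]] = {}
    annotations: dict = {}
    lineno = 1
    terminated = False
    for line in source:
        lineno += 1
        stripped = line.strip()
        if not stripped:
            continue
        if stripped == "//":
            terminated = True
            break
        if stripped.startswith("#"):
            annotations.setdefault("annotations", []).append(stripped)
            continue
        parts = stripped.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"malformed Stockholm row {stripped!r}", line=lineno)
        name, seq = parts
        if name not in chunks:
            order.append(name)
            chunks[name] = []
        chunks[name].append(seq)
    if not terminated:
        raise ParseError("Stockholm alignment not terminated by '//'")
    if not order:
        raise ParseError("Stockholm file contains no sequences")
    if metadata is not None:
        metadata.update(annotations)
    records = [SeqRecord(name, "", "".join(chunks[name])) for name in order]
    yield Alignment(records, metadata=annotations).validate()


def write_stockholm(alignments, sink: IO[str]) -> int:
    count = 0
    for alignment in _iter_alignments(alignments):
        alignment.validate()
        sink.write("# STOCKHOLM 1.0\n")
        width = max(len(rec.id) for rec in alignment.records) + 2
        for rec in alignment.records:
            sink.write(f"{rec.id:<{width}}{rec.sequence}\n")
        sink.write("//\n")
        count += len(alignment.records)
    return count


def _iter_alignments(alignments) -> Iterator[Alignment]:
    if isinstance(alignments, Alignment):
        yield alignments
    else:
        for item in alignments:
            if not isinstance(item, Alignment):
                raise ParseError(
                    f"MSA writers take Alignment objects, got {type(item).__name__}"
                )
            yield item
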