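"""Deterministic synthetic test and benchmark inputs for every format.

Each generated file is fully determined by its :class:`FixtureSpec`: the
pseudorandom stream is seeded from the format name, the record count and
the integer seed, so identical specs produce byte-identical files on any
platform.  Sequences are uniform random DNA, qualities uniform on
[0, 40]; MSA fixtures are equal-length gapped rows, tree fixtures random
binary topologies with branch lengths, GFF3/VCF fixtures sorted
non-overlapping features, and SAM fixtures a mix of forward and
reverse-strand reads under a minimal header.  None of this models real
error profiles or coverage structure — the fixtures exercise format
mechanics, not biology.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass
from pathlib import Path
from typing import IO

from .compression import open_auto
from .errors import BiofmtError

BASES = "ACGT"
MAX_FIXTURE_QUALITY = 40

SIZE_CLASSES = {"small": 100, "medium": 10_000, "large": 1_000_000}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic file; equal specs yield identical bytes."""

    format: str
    n_records: int = 10
    record_length: int = 50
    seed: int = 0
    compression: str | None = None  # None | "gz" | "bz2"

    def stream(self) -> random.Random:
        # string seeding hashes the bytes, stable across platforms and runs
        return random.Random(f"{self.format}/{self.n_records}/{self.record_length}/{self.seed}")


def _dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(length))


def _qualities(rng: random.Random, length: int) -> list[int]:
    return [rng.randint(0, MAX_FIXTURE_QUALITY) for _ in range(length)]


def _gapped(rng: random.Random, length: int) -> str:
    return "".join(
        "-" if rng.random() < 0.1 else rng.choice(BASES) for _ in range(length)
    )


def _random_newick(rng: random.Random, taxa: list[str]) -> str:
    """Random binary topology over ``taxa`` with two-decimal branch lengths."""

    def build(group: list[str]) -> str:
        if len(group) == 1:
            return f"{group[0]}:{rng.randint(1, 99) / 100:.2f}"
        split = rng.randint(1, len(group) - 1)
        left, right = build(group[:split]), build(group[split:])
        return f"({left},{right}):{rng.randint(1, 99) / 100:.2f}"

    shuffled = list(taxa)
    rng.shuffle(shuffled)
    if len(shuffled) == 1:
        return f"({shuffled[0]}:{rng.randint(1, 99) / 100:.2f});"
    return build(shuffled) + ";"


def _write_fastq(spec: FixtureSpec, rng: random.Random, sink: IO[str]) -> None:
    for i in range(spec.n_records):
        seq = _dna(rng, spec.record_length)
        qual = "".join(chr(q + 33) for q in _qualities(rng, spec.record_length))
        sink.write(f"@read_{i:04d} simulated\n{seq}\n+\n{qual}\n")


def _write_fasta(spec: FixtureSpec, rng: random.Random, sink: IO[str]) -> None:
    for i in range(spec.n_records):
        sink.write(f">read_{i:04d} simulated\n{_dna(rng, spec.record_length)}\n")


def _write_qual(spec: FixtureSpec, rng: random.Random, sink: IO[str]) -> None:
    for i in range(spec.n_records):
        scores = _qualities(rng, spec.record_length)
        sink.write(f">read_{i:04d} simulated\n")
        for j in range(0, len(scores), 20):
            sink.write(" ".join(str(q) for q in scores[j : j + 20]) + "\n")


def _msa_rows(spec: FixtureSpec, rng: random.Random) -> list[tuple[str, str]]:
    n = max(spec.n_records, 1)  # an alignment needs at least one row
    return [(f"seq_{i:03d}", _gapped(rng, spec.record_length)) for i in range(n)]


def _write_clustal(spec: FixtureSpec, rng: random.Random, sink: IO[str]) -> None:
    rows = _msa_rows(spec, rng)
    sink.write("CLUSTAL multiple sequence alignment\n\n")
    width = max(len(name) for name, _ in rows) + 3
    for start in range(0, spec.record_length or 1, 60):
        for name, seq in rows:
            sink.write(f"{name:<{width}}{seq[start:start + 60]}\n")
        sink.write("\n")


def _write_phylip(spec: FixtureSpec, rng: random.Random, sink: IO[str]) -> None:
    rows = _msa_rows(spec, rng)
    sink.write(f" {len(rows)} {spec.record_length}\n")
    for name, seq in rows:
        sink.write(f"{name:<10}{seq}\n")


def _write_stockholm(spec: FixtureSpec, rng: random.Random, sink: IO[str]) -> None:
    rows = _msa_rows(spec, rng)
    sink.write("# STOCKHOLM 1.0\n")
    width = max(len(name) for name, _ in rows) + 2
    for name, seq in rows:
        sink.write(f"{name:<{width}}{seq}\n")
    sink.write("//\n")


def _write_newick(spec: FixtureSpec, rng: random.Random, sink: IO[str]) -> None:
    n_taxa = max(2, min(spec.record_length // 5, 20))
    for _ in range(max(spec.n_records, 1)):
        taxa = [f"t{j + 1}" for j in range(n_taxa)]
        sink.write(_random_newick(rng, taxa) + "\n")


def _write_nexus(spec: FixtureSpec, rng: random.Random, sink: IO[str]) -> None:
    n_taxa = max(2, min(spec.record_length // 5, 20))
    sink.write("#NEXUS\nbegin trees;\n")
    for i in range(max(spec.n_records, 1)):
        taxa = [f"t{j + 1}" for j in range(n_taxa)]
        sink.write(f"  tree TREE{i + 1} = {_random_newick(rng, taxa)}\n")
    sink.write("end;\n")


def _write_gff3(spec: FixtureSpec, rng: random.Random, sink: IO[str]) -> None:
    sink.write("##gff-version 3\n")
    cursor = 1
    for i in range(spec.n_records):
        start = cursor + rng.randint(1, 50)
        end = start + rng.randint(0, max(spec.record_length, 1))
        cursor = end + 1  # sorted, non-overlapping
        strand = rng.choice("+-")
        ftype = rng.choice(["gene", "mRNA", "exon", "CDS"])
        sink.write(
            f"chr1\tbiofmt\t{ftype}\t{start}\t{end}\t{rng.randint(1, 1000)}\t"
            f"{strand}\t.\tID=feat_{i:04d};Name=synthetic_{i}\n"
        )


def _write_vcf(spec: FixtureSpec, rng: random.Random, sink: IO[str]) -> None:
    sink.write("##fileformat=VCFv4.2\n")
    sink.write("##contig=<ID=chr1,length=100000000>\n")
    sink.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    sink.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    pos = 0
    for i in range(spec.n_records):
        pos += rng.randint(5, 100)
        ref_len = rng.choice([1, 1, 1, 2, 3])  # mostly SNVs, some deletions
        ref = _dna(rng, ref_len)
        alt = rng.choice([b for b in BASES if b != ref[0]])
        sink.write(
            f"chr1\t{pos}\trs{i:04d}\t{ref}\t{alt}\t{rng.randint(10, 99)}\tPASS\t"
            f"DP={rng.randint(5, 200)}\n"
        )


def _write_sam(spec: FixtureSpec, rng: random.Random, sink: IO[str]) -> None:
    ref_length = 10_000 + 10 * spec.record_length
    sink.write("@HD\tVN:1.6\tSO:unsorted\n")
    sink.write(f"@SQ\tSN:chr1\tLN:{ref_length}\n")
    for i in range(spec.n_records):
        flag = 16 if rng.random() < 0.5 else 0  # half the reads map reversed
        seq = _dna(rng, spec.record_length)
        qual = "".join(chr(q + 33) for q in _qualities(rng, spec.record_length))
        pos = rng.randint(1, ref_length - spec.record_length)
        sink.write(
            f"read_{i:04d}\t{flag}\tchr1\t{pos}\t60\t{spec.record_length}M\t*\t0\t0\t"
            f"{seq}\t{qual}\tNM:i:0\n"
        )


def _write_bed(spec: FixtureSpec, rng: random.Random, sink: IO[str]) -> None:
    cursor = 0
    for i in range(spec.n_records):
        start = cursor + rng.randint(1, 50)
        end = start + rng.randint(1, max(spec.record_length, 1))
        cursor = end
        sink.write(f"chr1\t{start}\t{end}\tiv_{i:04d}\t{rng.randint(0, 1000)}\t"
                   f"{rng.choice('+-')}\n")


_GENERATORS = {
    "fastq": _write_fastq,
    "fasta": _write_fasta,
    "qual": _write_qual,
    "clustal": _write_clustal,
    "phylip": _write_phylip,
    "stockholm": _write_stockholm,
    "newick": _write_newick,
    "nexus": _write_nexus,
    "gff3": _write_gff3,
    "vcf": _write_vcf,
    "sam": _write_sam,
    "bed": _write_bed,
}

SUPPORTED_FORMATS = tuple(_GENERATORS)


def generate(spec: FixtureSpec, path: str | Path) -> Path:
    """Write the fixture described by ``spec`` to ``path`` and return it."""
    try:
        writer = _GENERATORS[spec.format]
    except KeyError:
        raise BiofmtError(f"no fixture generator for format {spec.format!r}") from None
    path = Path(path)
    if spec.compression and not path.name.endswith("." + spec.compression.lstrip(".")):
        path = path.with_name(path.name + "." + spec.compression.lstrip("."))
    with open_auto(str(path), "w") as sink:
        writer(spec, spec.stream(), sink)
    return path


def benchmark_input(
    format: str, size_class: str, seed: int, directory: str | Path
) -> Path:
    """A larger seeded input for benchmarking: ~1e2 / 1e4 / 1e6 records."""
    if size_class not in SIZE_CLASSES:
        raise BiofmtError(
            f"unknown size class {size_class!r}; choose from {sorted(SIZE_CLASSES)}"
        )
    n = SIZE_CLASSES[size_class]
    spec = FixtureSpec(format=format, n_records=n, seed=seed)
    return generate(spec, Path(directory) / f"bench_{format}_{size_class}{_ext(format)}")


def _ext(format: str) -> str:
    return {"gff3": ".gff", "stockholm": ".sto", "newick": ".nwk"}.get(format, f".{format}")


def write_manifest(entries: list[tuple[Path, FixtureSpec]], sink: IO[str]) -> None:
    """TSV manifest: path, format, n_records, seed, sha256 of the content."""
    sink.write("path\tformat\tn_records\tseed\tsha256\n")
    for path, spec in entries:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        sink.write(f"{path}\t{spec.format}\t{spec.n_records}\t{spec.seed}\t{digest}\n")
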