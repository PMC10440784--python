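"""The concrete conversion plugins and the unified ``convert`` dispatcher.

Every converter is a plain class following the plugin contract scanned by
:func:`biofmt.registry.discover_converters`: ``inputs``/``outputs`` declare
the port formats, every ``_method_<name>`` callable is an alternative
implementation of the same conversion, and ``default_method`` (or the
first method) is what runs when the user does not choose.  Methods of one
converter must be interchangeable — byte-identical outputs under identical
options — because the benchmark module times them against each other.

All file access goes through :func:`biofmt.compression.open_auto`, so every
converter transparently reads and writes gzip/bzip2 files.
"""

from __future__ import annotations

import shlex
import shutil
import subprocess
import time
from itertools import zip_longest
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator
from urllib.parse import unquote

from . import formats_io as fio
from .compression import open_auto
from .errors import (
    ConversionError,
    ExternalToolError,
    MissingExecutableError,
    PairingError,
    ParseError,
    UnknownMethodError,
)
from .registry import (
    ConversionPlan,
    ConverterSpec,
    Registry,
    default_formats,
    requires_tool,
)
from .formats_io.sequences import wrap

DEFAULT_WRAP = 80
#: constant Phred score assigned when a FASTA file is promoted to FASTQ
DUMMY_QUALITY = 40

QUALITY_LOSS = "quality information is lost when converting from FastQ to FastA"


def _normalize_header(text: str) -> str:
    """id + description exactly as the record-object pipeline renders them."""
    parts = text.split(None, 1)
    if not parts:
        raise ParseError("empty header line")
    description = parts[1].rstrip() if len(parts) > 1 else ""
    return f"{parts[0]} {description}" if description else parts[0]


@dataclass
class ConversionReport:
    """Outcome of one conversion run."""

    spec_name: str
    method: str
    records_in: int = 0
    records_out: int = 0
    lossy_warning: str | None = None
    elapsed: float = 0.0


# ----------------------------------------------------------------- plugins


class Fastq2Fasta:
    """Drop qualities from FASTQ reads.

    Three deliberately different mechanisms are provided so the benchmark
    framework has genuinely distinct candidates to time: a record-object
    pipeline, a four-line state machine and whole-buffer splitting.  All
    three must emit identical bytes for a given wrap width.
    """

    inputs = ("fastq",)
    outputs = ("fasta",)
    lossy = True
    lossy_detail = QUALITY_LOSS
    default_method = "records"

    def _method_records(self, inputs, outputs, options):
        wrap_width = options.get("wrap_width", DEFAULT_WRAP)
        with open_auto(inputs[0]) as src, open_auto(outputs[0], "w") as dst:
            count = 0
            for rec in fio.parse_records("fastq", src):
                dst.write(f">{rec.header}\n")
                for line in wrap(rec.sequence, wrap_width):
                    dst.write(line + "\n")
                count += 1
        return count, count

    def _method_quadruples(self, inputs, outputs, options):
        wrap_width = options.get("wrap_width", DEFAULT_WRAP)
        count = 0
        with open_auto(inputs[0]) as src, open_auto(outputs[0], "w") as dst:
            while True:
                header = src.readline()
                if not header:
                    break
                if not header.strip():
                    continue
                seq = src.readline().strip()
                plus = src.readline()
                src.readline()  # quality line, discarded
                if not plus.startswith("+"):
                    raise ParseError(f"expected '+' separator in {inputs[0]}")
                dst.write(">" + _normalize_header(header[1:]) + "\n")
                for line in wrap(seq, wrap_width):
                    dst.write(line + "\n")
                count += 1
        return count, count

    def _method_buffer(self, inputs, outputs, options):
        wrap_width = options.get("wrap_width", DEFAULT_WRAP)
        with open_auto(inputs[0]) as src:
            lines = [ln for ln in src.read().split("\n") if ln]
        if len(lines) % 4:
            raise ParseError(f"{inputs[0]}: line count is not a multiple of 4")
        count = 0
        with open_auto(outputs[0], "w") as dst:
            for i in range(0, len(lines), 4):
                if not lines[i + 2].startswith("+"):
                    raise ParseError(f"expected '+' separator in {inputs[0]}")
                dst.write(">" + _normalize_header(lines[i][1:]) + "\n")
                for line in wrap(lines[i + 1].strip(), wrap_width):
                    dst.write(line + "\n")
                count += 1
        return count, count


class Fastq2Qual:
    """Extract per-base qualities from FASTQ into a QUAL file."""

    inputs = ("fastq",)
    outputs = ("qual",)
    lossy = True
    lossy_detail = "sequence information is lost when converting from FastQ to QUAL"

    def _method_records(self, inputs, outputs, options):
        with open_auto(inputs[0]) as src, open_auto(outputs[0], "w") as dst:
            count = fio.write_records("qual", fio.parse_records("fastq", src), dst)
        return count, count


class Fastq2FastaQual:
    """Logical gate splitting FASTQ into FASTA plus QUAL in one pass.

    Lossless as a pair: together the two outputs carry everything a FASTQ
    record holds, so the gate round-trips through ``fasta_qual2fastq``.
    """

    inputs = ("fastq",)
    outputs = ("fasta", "qual")

    def _method_records(self, inputs, outputs, options):
        wrap_width = options.get("wrap_width", DEFAULT_WRAP)
        count = 0
        with open_auto(inputs[0]) as src, open_auto(outputs[0], "w") as fa, open_auto(
            outputs[1], "w"
        ) as qa:
            for rec in fio.parse_records("fastq", src):
                fio.write_records("fasta", [rec], fa, wrap_width=wrap_width)
                fio.write_records("qual", [rec], qa)
                count += 1
        return count, count


class FastaQual2Fastq:
    """Logical gate merging a FASTA and a QUAL file back into FASTQ.

    Both inputs must list the same record ids in the same order with
    matching lengths; the first mismatch is reported by record index.
    """

    inputs = ("fasta", "qual")
    outputs = ("fastq",)

    def _method_records(self, inputs, outputs, options):
        count = 0
        with open_auto(inputs[0]) as fa, open_auto(inputs[1]) as qa, open_auto(
            outputs[0], "w"
        ) as dst:
            seqs = fio.parse_records("fasta", fa)
            quals = fio.parse_records("qual", qa)
            for k, (srec, qrec) in enumerate(zip_longest(seqs, quals), start=1):
                if srec is None or qrec is None:
                    raise PairingError(
                        f"record {k}: FASTA and QUAL hold different record counts"
                    )
                if srec.id != qrec.id:
                    raise PairingError(
                        f"record {k}: FASTA id {srec.id!r} != QUAL id {qrec.id!r}"
                    )
                if len(srec.sequence) != len(qrec.quality or []):
                    raise PairingError(
                        f"record {k} ({srec.id!r}): sequence length "
                        f"{len(srec.sequence)} != quality length {len(qrec.quality or [])}"
                    )
                merged = fio.SeqRecord(
                    srec.id, srec.description, srec.sequence, qrec.quality
                )
                fio.write_records("fastq", [merged], dst)
                count += 1
        return count, count


class Fasta2Fastq:
    """Promote FASTA to FASTQ with a constant placeholder quality.

    Every base receives Phred 40 ('I'): a deterministic, clearly documented
    placeholder, since FASTA carries no quality information.
    """

    inputs = ("fasta",)
    outputs = ("fastq",)
    default_method = "records"

    def _method_records(self, inputs, outputs, options):
        quality = options.get("dummy_quality", DUMMY_QUALITY)
        with open_auto(inputs[0]) as src, open_auto(outputs[0], "w") as dst:
            count = 0
            for rec in fio.parse_records("fasta", src):
                rec.quality = [quality] * len(rec.sequence)
                fio.write_records("fastq", [rec], dst)
                count += 1
        return count, count

    def _method_linewise(self, inputs, outputs, options):
        quality = chr(options.get("dummy_quality", DUMMY_QUALITY) + 33)
        count = 0
        header: str | None = None
        chunks: list[str] = []

        with open_auto(inputs[0]) as src, open_auto(outputs[0], "w") as dst:

            def flush():
                nonlocal count
                if header is None:
                    return
                seq = "".join(chunks)
                dst.write(f"@{header}\n{seq}\n+\n{quality * len(seq)}\n")
                count += 1

            for line in src:
                if line.startswith(">"):
                    flush()
                    header = _normalize_header(line[1:])
                    chunks = []
                elif line.strip():
                    chunks.append(line.strip())
            flush()
        return count, count


class _AlignmentConverter:
    """Shared machinery for single-alignment format conversions."""

    source_format: str
    target_format: str

    def _method_records(self, inputs, outputs, options):
        writer_options = {}
        if self.target_format in {"fasta"}:
            writer_options["wrap_width"] = options.get("wrap_width", DEFAULT_WRAP)
        with open_auto(inputs[0]) as src, open_auto(outputs[0], "w") as dst:
            count_in = 0
            count_out = 0
            for alignment in self._read(src):
                count_in += len(alignment)
                count_out += self._write(alignment, dst, writer_options)
        return count_in, count_out

    def _read(self, src) -> Iterator[fio.Alignment]:
        if self.source_format == "fasta":
            records = list(fio.parse_records("fasta", src))
            if records:
                yield fio.Alignment(records).validate()
        else:
            yield from fio.parse_records(self.source_format, src)

    def _write(self, alignment: fio.Alignment, dst, writer_options) -> int:
        if self.target_format == "fasta":
            return fio.write_records("fasta", alignment.records, dst, **writer_options)
        return fio.write_records(self.target_format, alignment, dst, **writer_options)


class Clustal2Fasta(_AlignmentConverter):
    inputs = ("clustal",)
    outputs = ("fasta",)
    source_format, target_format = "clustal", "fasta"


class Fasta2Clustal(_AlignmentConverter):
    inputs = ("fasta",)
    outputs = ("clustal",)
    source_format, target_format = "fasta", "clustal"


class Fasta2Phylip(_AlignmentConverter):
    inputs = ("fasta",)
    outputs = ("phylip",)
    source_format, target_format = "fasta", "phylip"


class Phylip2Fasta(_AlignmentConverter):
    inputs = ("phylip",)
    outputs = ("fasta",)
    source_format, target_format = "phylip", "fasta"


class Fasta2Stockholm(_AlignmentConverter):
    inputs = ("fasta",)
    outputs = ("stockholm",)
    source_format, target_format = "fasta", "stockholm"


class Stockholm2Fasta(_AlignmentConverter):
    inputs = ("stockholm",)
    outputs = ("fasta",)
    source_format, target_format = "stockholm", "fasta"


class Clustal2Phylip(_AlignmentConverter):
    """Direct CLUSTAL to PHYLIP edge; also reachable via FASTA in two hops,
    with record-identical results (both are lossless on ids up to PHYLIP's
    10-character truncation)."""

    inputs = ("clustal",)
    outputs = ("phylip",)
    source_format, target_format = "clustal", "phylip"


class Newick2Nexus:
    inputs = ("newick",)
    outputs = ("nexus",)

    def _method_records(self, inputs, outputs, options):
        with open_auto(inputs[0]) as src, open_auto(outputs[0], "w") as dst:
            count = 0
            for doc in fio.parse_records("newick", src):
                count += len(doc.trees)
                fio.write_records("nexus", doc, dst)
        return count, count


class Nexus2Newick:
    """Flatten NEXUS trees to plain newick, applying the Translate table."""

    inputs = ("nexus",)
    outputs = ("newick",)

    def _method_records(self, inputs, outputs, options):
        with open_auto(inputs[0]) as src, open_auto(outputs[0], "w") as dst:
            count = 0
            for doc in fio.parse_records("nexus", src):
                count += len(doc.trees)
                fio.write_records("newick", doc, dst)
        return count, count


class Gff32Bed:
    """GFF3 features to 6-column BED (1-based inclusive -> 0-based half-open)."""

    inputs = ("gff3",)
    outputs = ("bed",)
    lossy = True
    lossy_detail = "source, type, phase and attributes are lost when converting GFF3 to BED"
    default_method = "records"

    def _method_records(self, inputs, outputs, options):
        with open_auto(inputs[0]) as src, open_auto(outputs[0], "w") as dst:
            count = 0
            for feature in fio.parse_records("gff3", src):
                fio.write_records("bed", [fio.gff3_to_interval(feature)], dst)
                count += 1
        return count, count

    def _method_linewise(self, inputs, outputs, options):
        # column shuffling on raw text; must match _method_records byte-for-byte
        count = 0
        with open_auto(inputs[0]) as src, open_auto(outputs[0], "w") as dst:
            for line in src:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) != 9:
                    raise ParseError(f"GFF3 row has {len(f)} columns, expected 9")
                name = "."
                for chunk in f[8].split(";"):
                    key, _, value = chunk.strip().partition("=")
                    if unquote(key) == "ID":
                        name = unquote(value)
                        break
                start = int(f[3]) - 1
                end = int(f[4])
                if start < 0 or end <= start:
                    raise ParseError(f"invalid GFF3 coordinates {f[3]}..{f[4]}")
                strand = f[6] if f[6] in "+-" else "."
                score = f[5] if f[5] else "."
                dst.write(f"{f[0]}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
                count += 1
        return count, count


class Vcf2Bed:
    """VCF variants to BED intervals spanning the reference allele."""

    inputs = ("vcf",)
    outputs = ("bed",)
    lossy = True
    lossy_detail = "alleles, filters and INFO are lost when converting VCF to BED"

    def _method_records(self, inputs, outputs, options):
        with open_auto(inputs[0]) as src, open_auto(outputs[0], "w") as dst:
            count = 0
            for record in fio.parse_records("vcf", src):
                fio.write_records("bed", [fio.variant_to_interval(record)], dst)
                count += 1
        return count, count


class _SamReads:
    """Shared read-extraction for SAM exports.

    Secondary (0x100) and supplementary (0x800) alignments are skipped so
    a read appears at most once, and reverse-strand reads (0x10) are
    restored to sequencing orientation.
    """

    def _reads(self, src) -> Iterator[tuple[int, fio.SeqRecord]]:
        for record in fio.parse_records("sam", src):
            rec = fio.sam_to_seqrecord(record)
            yield (1, rec) if rec is not None else (1, None)


class Sam2Fastq(_SamReads):
    inputs = ("sam",)
    outputs = ("fastq",)
    lossy = True
    lossy_detail = "alignment positions, CIGAR strings and tags are lost when converting SAM to FastQ"

    def _method_records(self, inputs, outputs, options):
        count_in = count_out = 0
        with open_auto(inputs[0]) as src, open_auto(outputs[0], "w") as dst:
            for n, rec in self._reads(src):
                count_in += n
                if rec is not None and rec.quality is not None:
                    count_out += fio.write_records("fastq", [rec], dst)
        return count_in, count_out


class Sam2Fasta(_SamReads):
    inputs = ("sam",)
    outputs = ("fasta",)
    lossy = True
    lossy_detail = "alignments and qualities are lost when converting SAM to FastA"

    def _method_records(self, inputs, outputs, options):
        wrap_width = options.get("wrap_width", DEFAULT_WRAP)
        count_in = count_out = 0
        with open_auto(inputs[0]) as src, open_auto(outputs[0], "w") as dst:
            for n, rec in self._reads(src):
                count_in += n
                if rec is not None:
                    count_out += fio.write_records(
                        "fasta", [rec], dst, wrap_width=wrap_width
                    )
        return count_in, count_out


class Sam2Bam:
    """SAM to BAM through the external-tool method contract.

    The command template lives in configuration (``command_template``
    option), not code, so deployments can swap in any samtools-compatible
    backend.  ``{input}`` and ``{output}`` placeholders are substituted,
    the executable's presence is checked first, and a nonzero exit status
    surfaces the captured stderr.
    """

    inputs = ("sam",)
    outputs = ("bam",)
    command_template = "samtools view -b -o {output} {input}"

    @requires_tool("samtools")
    def _method_samtools(self, inputs, outputs, options):
        template = options.get("command_template", self.command_template)
        command = template.format(input=inputs[0], output=outputs[0])
        argv = shlex.split(command)
        if shutil.which(argv[0]) is None:
            raise MissingExecutableError(argv[0])
        proc = subprocess.run(argv, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalToolError(command, proc.returncode, proc.stderr)
        if not Path(outputs[0]).exists():
            raise ExternalToolError(command, 0, "command succeeded but wrote no output")
        with open(inputs[0]) as src:
            count = sum(1 for line in src if line.strip() and not line.startswith("@"))
        return count, count


#: every stock plugin, in registration order
PLUGINS: tuple[type, ...] = (
    Fastq2Fasta,
    Fastq2Qual,
    Fastq2FastaQual,
    FastaQual2Fastq,
    Fasta2Fastq,
    Clustal2Fasta,
    Fasta2Clustal,
    Fasta2Phylip,
    Phylip2Fasta,
    Fasta2Stockholm,
    Stockholm2Fasta,
    Clustal2Phylip,
    Newick2Nexus,
    Nexus2Newick,
    Gff32Bed,
    Vcf2Bed,
    Sam2Fastq,
    Sam2Fasta,
    Sam2Bam,
)


def default_registry() -> Registry:
    """The stock registry: all default formats plus all stock plugins."""
    registry = Registry()
    for descriptor in default_formats():
        registry.register_format(descriptor)
    registry.register_plugins(PLUGINS)
    return registry


# ---------------------------------------------------------------- dispatch


def convert(
    registry: Registry,
    conversion: str | ConverterSpec,
    inputs: list[str],
    outputs: list[str],
    method: str = "default",
    options: dict | None = None,
) -> ConversionReport:
    """Run one conversion and return its :class:`ConversionReport`.

    ``method`` may be ``"default"`` or any member of the spec's method
    list.  Compressed inputs and outputs are handled transparently from
    their extensions.
    """
    spec = (
        registry.get_converter(conversion)
        if isinstance(conversion, str)
        else conversion
    )
    if method == "default":
        method = spec.default_method
    if method not in spec.methods:
        raise UnknownMethodError(method, spec.methods)
    if len(inputs) != len(spec.inputs) or len(outputs) != len(spec.outputs):
        raise ConversionError(
            f"{spec.name} takes {len(spec.inputs)} input(s) and "
            f"{len(spec.outputs)} output(s); got {len(inputs)} and {len(outputs)}"
        )
    executable = spec.requires_external.get(method)
    if executable and shutil.which(executable) is None:
        raise MissingExecutableError(executable)
    if spec.plugin is None:
        raise ConversionError(f"converter {spec.name!r} has no executable plugin")
    func = getattr(spec.plugin(), f"_method_{method}")
    start = time.perf_counter()
    records_in, records_out = func(list(inputs), list(outputs), options or {})
    elapsed = time.perf_counter() - start
    return ConversionReport(
        spec_name=spec.name,
        method=method,
        records_in=records_in,
        records_out=records_out,
        lossy_warning=spec.lossy_detail if spec.lossy else None,
        elapsed=elapsed,
    )


def fastq_gate(
    registry: Registry,
    fastq_path: str,
    fasta_path: str | None = None,
    qual_path: str | None = None,
    options: dict | None = None,
) -> ConversionReport:
    """Split a FASTQ file into its FASTA and/or QUAL components.

    With both outputs this is the lossless ``fastq2fasta_qual`` gate; with
    a single output the corresponding lossy single-port converter runs and
    the report's warning names what is discarded.
    """
    if fasta_path and qual_path:
        return convert(
            registry, "fastq2fasta_qual", [fastq_path], [fasta_path, qual_path],
            options=options,
        )
    if fasta_path:
        return convert(registry, "fastq2fasta", [fastq_path], [fasta_path], options=options)
    if qual_path:
        return convert(registry, "fastq2qual", [fastq_path], [qual_path], options=options)
    raise ConversionError("fastq_gate needs at least one of fasta_path / qual_path")


def run_plan(
    registry: Registry,
    plan: ConversionPlan,
    input_path: str,
    output_path: str,
    workdir: str,
    options: dict | None = None,
) -> list[ConversionReport]:
    """Execute a transitive conversion plan through intermediate files.

    Intermediates are written into ``workdir`` using each intermediate
    format's canonical extension; the final step writes ``output_path``.
    """
    if not plan.steps:
        raise ConversionError("cannot execute an empty conversion plan")
    reports = []
    current = input_path
    stem = Path(input_path).stem
    for i, step in enumerate(plan.steps):
        if i == len(plan.steps) - 1:
            target = output_path
        else:
            ext = registry.get_format(step.outputs[0]).primary_extension
            target = str(Path(workdir) / f"{stem}.step{i}{ext}")
        reports.append(convert(registry, step, [current], [target], options=options))
        current = target
    return reports
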