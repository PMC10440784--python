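"""Format registry, converter discovery and the conversion graph.

The registry owns three things:

* **format descriptors** — a named file format with its filename extensions
  and a broad domain tag (node of the conversion graph);
* **converter specs** — registered conversions between formats, each exposing
  one or more named methods with a designated default (edge of the graph;
  a converter with several inputs or outputs is a hyperedge, a "logical
  gate");
* **the conversion graph** itself, supporting extension-based inference of
  the requested conversion, shortest transitive path planning, and a DOT
  export.

Converters are not registered by hand: plugin classes are scanned by
:func:`discover_converters`, which extracts the conversion name, the
input/output formats and the method list from the class definition alone.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import (
    ExtensionConflictError,
    InvalidConverterError,
    NoConverterError,
    NoPathError,
    RegistrationError,
    UnresolvableExtensionError,
)

#: prefix that marks a plugin callable as a conversion method
METHOD_PREFIX = "_method_"

#: compression suffixes peeled before format inference, mapped to codec names
COMPRESSION_SUFFIXES = {".gz": "gzip", ".bz2": "bzip2"}

DOMAINS = frozenset(
    {
        "sequencing",
        "alignment-msa",
        "read-alignment",
        "phylogeny",
        "annotation",
        "variant",
        "other",
    }
)


@dataclass(frozen=True)
class FormatDescriptor:
    """A registered file format: a graph node.

    Parameters
    ----------
    name:
        Short lowercase token, unique across the registry (``"fastq"``).
    extensions:
        Filename extensions owned by the format, lowercase, each beginning
        with a dot and excluding compression suffixes.  Order is preserved:
        the first extension is the canonical one used when an output
        filename must be invented.
    domain:
        Broad field the format belongs to; one of :data:`DOMAINS`.
    binary:
        Whether the on-disk representation is binary (e.g. BAM).
    """

    name: str
    extensions: tuple[str, ...]
    domain: str = "other"
    binary: bool = False

    def __post_init__(self) -> None:
        if not self.name or self.name != self.name.lower() or " " in self.name:
            raise RegistrationError(f"format name must be a lowercase token: {self.name!r}")
        object.__setattr__(self, "extensions", tuple(dict.fromkeys(self.extensions)))
        if not self.extensions:
            raise RegistrationError(f"format {self.name!r} must register at least one extension")
        for ext in self.extensions:
            if not ext.startswith(".") or ext != ext.lower():
                raise RegistrationError(
                    f"extension {ext!r} of format {self.name!r} must be lowercase and dotted"
                )
            if ext in COMPRESSION_SUFFIXES:
                raise RegistrationError(
                    f"{ext!r} is a compression suffix and cannot name a format"
                )
        if self.domain not in DOMAINS:
            raise RegistrationError(f"unknown domain {self.domain!r} for format {self.name!r}")

    @property
    def primary_extension(self) -> str:
        """The first registered extension, used for implicit output naming."""
        return self.extensions[0]


@dataclass(frozen=True)
class ConverterSpec:
    """A registered conversion: a (hyper)edge of the conversion graph.

    The canonical name is derived from the port formats: input names joined
    with ``_``, then ``2``, then output names joined with ``_`` —
    ``fastq2fasta``, ``fastq2fasta_qual``, ``fasta_qual2fastq``.
    """

    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    methods: tuple[str, ...]
    default_method: str
    lossy: bool = False
    lossy_detail: str = ""
    requires_external: dict[str, str] = field(default_factory=dict, compare=False)
    plugin: type | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.inputs or not self.outputs:
            raise RegistrationError("converter needs at least one input and one output format")
        if not self.methods:
            raise InvalidConverterError(f"converter {self.name!r} declares no methods")
        if self.default_method not in self.methods:
            raise InvalidConverterError(
                f"default method {self.default_method!r} of {self.name!r} "
                f"is not among its methods {self.methods}"
            )

    @property
    def name(self) -> str:
        return "_".join(self.inputs) + "2" + "_".join(self.outputs)

    @property
    def is_gate(self) -> bool:
        """True for multi-input or multi-output conversions ("logical gates")."""
        return len(self.inputs) > 1 or len(self.outputs) > 1


@dataclass(frozen=True)
class ConversionPlan:
    """An ordered chain of single-port conversion steps."""

    steps: tuple[ConverterSpec, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.steps, self.steps[1:]):
            if a.outputs != b.inputs or len(a.outputs) != 1:
                raise RegistrationError(
                    f"steps {a.name!r} and {b.name!r} are not composable"
                )

    @property
    def lossy(self) -> bool:
        return any(step.lossy for step in self.steps)

    @property
    def formats(self) -> tuple[str, ...]:
        """The chain of format names visited, source first."""
        if not self.steps:
            return ()
        return self.steps[0].inputs + tuple(s.outputs[0] for s in self.steps)


def spec_from_plugin(cls: type) -> ConverterSpec:
    """Build a :class:`ConverterSpec` from a plugin class.

    The plugin contract: the class declares its ports either through
    ``inputs``/``outputs`` tuples of format names or through a parseable
    ``conversion`` name (``"a2b"``); every callable whose name starts with
    ``_method_`` is a conversion method, in declaration order; an optional
    ``default_method`` attribute picks the default, otherwise the first
    method is the default.
    """
    if getattr(cls, "inputs", None) and getattr(cls, "outputs", None):
        inputs = tuple(cls.inputs)
        outputs = tuple(cls.outputs)
    else:
        name = getattr(cls, "conversion", None) or cls.__name__.lower()
        if "2" not in name:
            raise InvalidConverterError(
                f"plugin {cls.__name__} declares neither ports nor a parseable A2B name"
            )
        left, _, right = name.partition("2")
        inputs = tuple(left.split("_"))
        outputs = tuple(right.split("_"))

    # walk the MRO base-first so mixin-provided methods are discovered;
    # a subclass override keeps the base's declaration position
    collected: dict[str, object] = {}
    for klass in reversed(cls.__mro__):
        for attr, value in vars(klass).items():
            if attr.startswith(METHOD_PREFIX) and callable(value):
                collected[attr] = value
    methods: list[str] = []
    external: dict[str, str] = {}
    for attr, value in collected.items():
        method = attr[len(METHOD_PREFIX):]
        methods.append(method)
        tool = getattr(value, "_external_tool", None)
        if tool:
            external[method] = tool
    if not methods:
        raise InvalidConverterError(
            f"plugin {cls.__name__} has no {METHOD_PREFIX}* methods"
        )
    default = getattr(cls, "default_method", None) or methods[0]
    return ConverterSpec(
        inputs=inputs,
        outputs=outputs,
        methods=tuple(methods),
        default_method=default,
        lossy=bool(getattr(cls, "lossy", False)),
        lossy_detail=getattr(cls, "lossy_detail", ""),
        requires_external=external,
        plugin=cls,
    )


def discover_converters(definitions: Iterable[type]) -> list[ConverterSpec]:
    """Scan plugin classes and return their specs, in declaration order."""
    return [spec_from_plugin(cls) for cls in definitions]


class Registry:
    """Mutable collection of formats and converters."""

    def __init__(self) -> None:
        self._formats: dict[str, FormatDescriptor] = {}
        self._by_extension: dict[str, str] = {}
        self._converters: dict[str, ConverterSpec] = {}
        self._by_ports: dict[tuple[tuple[str, ...], tuple[str, ...]], ConverterSpec] = {}

    # ------------------------------------------------------------------ formats

    def register_format(self, descriptor: FormatDescriptor) -> None:
        if descriptor.name in self._formats:
            raise RegistrationError(f"format {descriptor.name!r} is already registered")
        for ext in descriptor.extensions:
            owner = self._by_extension.get(ext)
            if owner is not None:
                raise ExtensionConflictError(
                    f"extension {ext!r} already claimed by format {owner!r}; "
                    f"cannot also assign it to {descriptor.name!r}"
                )
        self._formats[descriptor.name] = descriptor
        for ext in descriptor.extensions:
            self._by_extension[ext] = descriptor.name

    def get_format(self, name: str) -> FormatDescriptor:
        try:
            return self._formats[name]
        except KeyError:
            raise RegistrationError(f"unknown format {name!r}") from None

    def format_for_extension(self, extension: str) -> str:
        try:
            return self._by_extension[extension.lower()]
        except KeyError:
            raise UnresolvableExtensionError(
                f"extension {extension!r} matches no registered format; "
                "use explicit mode to name the conversion"
            ) from None

    @property
    def formats(self) -> tuple[FormatDescriptor, ...]:
        return tuple(self._formats.values())

    def infer_format(self, path: str) -> tuple[str, str | None]:
        """Infer ``(format-name, codec-or-None)`` from a filename.

        Compression suffixes are peeled first, then the remaining final
        extension is resolved against the registry.  The file need not
        exist.
        """
        name = str(path)
        codec = None
        lowered = name.lower()
        for suffix, codec_name in COMPRESSION_SUFFIXES.items():
            if lowered.endswith(suffix):
                codec = codec_name
                name = name[: -len(suffix)]
                lowered = name.lower()
                break
        dot = lowered.rfind(".")
        if dot < 0:
            raise UnresolvableExtensionError(
                f"filename {path!r} has no extension; use explicit mode"
            )
        return self.format_for_extension(lowered[dot:]), codec

    # --------------------------------------------------------------- converters

    def register_converter(self, spec: ConverterSpec) -> None:
        for fmt in spec.inputs + spec.outputs:
            self.get_format(fmt)  # every edge endpoint must be a node
        if spec.name in self._converters:
            raise RegistrationError(f"converter {spec.name!r} is already registered")
        ports = (spec.inputs, spec.outputs)
        if ports in self._by_ports:
            raise RegistrationError(
                f"a converter for ports {ports} is already registered"
            )
        self._converters[spec.name] = spec
        self._by_ports[ports] = spec

    def register_plugins(self, definitions: Iterable[type]) -> list[ConverterSpec]:
        """Discover plugin classes and register them; idempotent per class."""
        specs = []
        for spec in discover_converters(definitions):
            existing = self._converters.get(spec.name)
            if existing is not None and existing == spec:
                specs.append(existing)
                continue
            self.register_converter(spec)
            specs.append(spec)
        return specs

    def get_converter(self, name: str) -> ConverterSpec:
        try:
            return self._converters[name]
        except KeyError:
            raise NoConverterError(f"no converter named {name!r} is registered") from None

    @property
    def converters(self) -> tuple[ConverterSpec, ...]:
        return tuple(self._converters.values())

    def resolve_conversion(
        self, input_paths: list[str], output_paths: list[str]
    ) -> ConverterSpec:
        """Implicit mode: infer the converter from filename extensions."""
        inputs = tuple(self.infer_format(p)[0] for p in input_paths)
        outputs = tuple(self.infer_format(p)[0] for p in output_paths)
        spec = self._by_ports.get((inputs, outputs))
        if spec is not None:
            return spec
        message = (
            f"no converter registered for {'_'.join(inputs)} -> {'_'.join(outputs)}"
        )
        if len(inputs) == 1 and len(outputs) == 1:
            try:
                plan = self.find_path(inputs[0], outputs[0])
            except NoPathError:
                plan = None
            if plan is not None and plan.steps:
                chain = " -> ".join(plan.formats)
                message += (
                    f"; a transitive path exists ({chain}): rerun with the"
                    " transitive option (-a)"
                )
        raise NoConverterError(message)

    # -------------------------------------------------------------------- graph

    def _single_port_edges(self) -> dict[str, dict[str, ConverterSpec]]:
        adjacency: dict[str, dict[str, ConverterSpec]] = {}
        for spec in self._converters.values():
            if len(spec.inputs) == 1 and len(spec.outputs) == 1:
                adjacency.setdefault(spec.inputs[0], {})[spec.outputs[0]] = spec
        return adjacency

    def find_path(self, source: str, target: str) -> ConversionPlan:
        """Minimum-hop conversion plan from ``source`` to ``target``.

        Only single-input/single-output converters participate (gates have
        no defined chaining semantics).  Ties between equally short paths
        are broken by the lexicographically smallest sequence of
        intermediate format names, making the result deterministic across
        runs and platforms.
        """
        self.get_format(source)
        self.get_format(target)
        if source == target:
            return ConversionPlan(())
        adjacency = self._single_port_edges()
        # Dijkstra on the key (hops, name-sequence); the product order is
        # monotone under path extension, so the first settle is optimal.
        heap: list[tuple[int, tuple[str, ...], str, tuple[ConverterSpec, ...]]] = [
            (0, (), source, ())
        ]
        settled: set[str] = set()
        while heap:
            hops, names, node, steps = heapq.heappop(heap)
            if node in settled:
                continue
            settled.add(node)
            if node == target:
                return ConversionPlan(steps)
            for nxt in sorted(adjacency.get(node, {})):
                if nxt not in settled:
                    spec = adjacency[node][nxt]
                    heapq.heappush(
                        heap, (hops + 1, names + (nxt,), nxt, steps + (spec,))
                    )
        raise NoPathError(f"no conversion path from {source!r} to {target!r}")

    _DOMAIN_COLORS = {
        "sequencing": "lightblue",
        "alignment-msa": "palegreen",
        "read-alignment": "khaki",
        "phylogeny": "plum",
        "annotation": "lightsalmon",
        "variant": "lightpink",
        "other": "white",
    }

    def export_graph(self, sink: IO[str], annotate: bool = False) -> None:
        """Emit the conversion graph in DOT syntax.

        Gates are rendered through an anonymous point-shaped junction node
        with edges from every input format and to every output format.
        With ``annotate`` nodes are coloured by domain and sized by degree.
        """
        degree: dict[str, int] = {name: 0 for name in self._formats}
        for spec in self._converters.values():
            for fmt in set(spec.inputs) | set(spec.outputs):
                degree[fmt] = degree.get(fmt, 0) + 1

        sink.write("digraph conversions {\n")
        sink.write("  rankdir=LR;\n")
        for fmt in self._formats.values():
            attrs = []
            if annotate:
                color = self._DOMAIN_COLORS.get(fmt.domain, "white")
                attrs.append(f'style=filled, fillcolor="{color}"')
                attrs.append(f"penwidth={1 + degree.get(fmt.name, 0) / 2:.1f}")
            attr_text = f" [{', '.join(attrs)}]" if attrs else ""
            sink.write(f'  "{fmt.name}"{attr_text};\n')
        gate_index = 0
        for spec in self._converters.values():
            if not spec.is_gate:
                sink.write(
                    f'  "{spec.inputs[0]}" -> "{spec.outputs[0]}" [label="{spec.name}"];\n'
                )
                continue
            junction = f"gate{gate_index}"
            gate_index += 1
            sink.write(f'  {junction} [shape=point, label=""];\n')
            for fmt in spec.inputs:
                sink.write(f'  "{fmt}" -> {junction};\n')
            for fmt in spec.outputs:
                sink.write(f'  {junction} -> "{fmt}" [label="{spec.name}"];\n')
        sink.write("}\n")

    # ------------------------------------------------------------------- export

    def dump_formats_tsv(self, sink: IO[str]) -> None:
        sink.write("format\textensions\tdomain\n")
        for fmt in sorted(self._formats.values(), key=lambda f: f.name):
            sink.write(f"{fmt.name}\t{','.join(sorted(fmt.extensions))}\t{fmt.domain}\n")

    def dump_conversions_tsv(self, sink: IO[str]) -> None:
        sink.write("conversion\tinputs\toutputs\tmethods\tdefault\n")
        for spec in sorted(self._converters.values(), key=lambda s: s.name):
            sink.write(
                f"{spec.name}\t{','.join(spec.inputs)}\t{','.join(spec.outputs)}\t"
                f"{','.join(spec.methods)}\t{spec.default_method}\n"
            )


def requires_tool(executable: str):
    """Mark a plugin method as shelling out to an external executable."""

    def decorator(func):
        func._external_tool = executable
        return func

    return decorator


def default_formats() -> list[FormatDescriptor]:
    """The stock format table: community-conventional extensions, one format
    per extension so that implicit mode stays deterministic."""
    table = [
        ("fastq", (".fastq", ".fq"), "sequencing", False),
        ("fasta", (".fasta", ".fa", ".fna"), "sequencing", False),
        ("qual", (".qual",), "sequencing", False),
        ("clustal", (".clustal", ".aln", ".clw"), "alignment-msa", False),
        ("phylip", (".phylip", ".phy"), "alignment-msa", False),
        ("stockholm", (".sto", ".stk", ".stockholm"), "alignment-msa", False),
        ("nexus", (".nexus", ".nx", ".nxs"), "phylogeny", False),
        ("newick", (".newick", ".nw", ".nwk"), "phylogeny", False),
        ("gff3", (".gff", ".gff3"), "annotation", False),
        ("bed", (".bed",), "annotation", False),
        ("vcf", (".vcf",), "variant", False),
        ("sam", (".sam",), "read-alignment", False),
        ("bam", (".bam",), "read-alignment", True),
    ]
    return [
        FormatDescriptor(name, exts, domain, binary)
        for name, exts, domain, binary in table
    ]
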