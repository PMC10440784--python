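# Methods

This note documents the models, conventions and numerical choices behind
`biofmt`: what the conversion framework assumes, what the synthetic data
does and does not emulate, and where genuinely open design questions were
settled and why.

## The conversion graph

Formats are nodes; converters are directed edges. A converter's canonical
name is derived from its ports (`fastq2fasta`, `fasta_qual2fastq`), so the
name, the port lists and the registry's extension table are mutually
consistent by construction: building filenames from a converter's ports
and resolving them implicitly yields the same converter back. The
registry enforces one format per extension — ambiguous extensions are
rejected at registration time rather than resolved heuristically, which
keeps implicit mode deterministic. Compression suffixes (`.gz`, `.bz2`)
are peeled before extension resolution and are never format extensions
themselves.

The graph is directed and **contains cycles** (`fastq ↔ fasta`,
`clustal ↔ fasta`, `newick ↔ nexus`). Some descriptions of conversion
inventories call such graphs acyclic; with mutually inverse converters
registered that is not literally attainable, and correctness is preferred
over terminology here. Cycles are harmless to the planner, which never
revisits a settled node.

### Transitive planning

`find_path` searches only single-input/single-output edges; multi-port
gates are excluded because chaining semantics for a hyperedge (which
output feeds the next step?) are undefined. The search is a Dijkstra
variant on the composite key *(hop count, sequence of intermediate format
names)*: the lexicographic product order is monotone under path
extension, so the first time the target is settled the plan is both
minimum-hop and deterministically tie-broken across platforms and hash
seeds. Path length is unbounded — any reachable target is accepted, not
just two-hop routes. A brute-force simple-path enumeration over random
graphs of up to 8 nodes serves as the independent oracle for this search
in the tests and the acceptance script (1000 seeded graphs). Plans
carry a `lossy` flag, the OR of step lossiness, and the CLI prints the
combined loss warning before executing a lossy route.

## Format dialects

No public format fixes every layout detail, so writers commit to one
deterministic dialect and parsers accept the common variants:

* **FASTQ** — strict four-line records, Phred+33 ("Sanger") quality
  encoding on both read and write. Legacy Phred+64 input is decoded by
  passing `offset=64` explicitly; there is no autodetection, because on
  modern data a +64 guess is almost always wrong. Valid scores span
  [0, 93], the printable range.
* **FASTA** — writer wraps sequence lines at 80 columns (option
  `wrap_width`, 0 disables); parser accepts any wrapping. Record ids are
  the first whitespace-delimited token; the rest of the header line is
  the description.
* **QUAL** — `>`-headed blocks of space-separated integers, 20 per line.
* **PHYLIP** — writer emits strict sequential layout with 10-column
  padded names; names longer than 10 characters are truncated, and a
  collision after truncation is an error naming the colliding ids (a
  silent collision would corrupt the alignment). The parser accepts both
  sequential and interleaved input: continuation lines are assigned
  round-robin when every row is equally incomplete and the line count
  divides evenly, else fill-in-order.
* **CLUSTAL** — 60-column blocks; conservation lines (leading
  whitespace) are skipped on read.
* **Stockholm** — single-block output with the `# STOCKHOLM 1.0` header
  and `//` terminator; `#=` annotation lines are collected as metadata.
* **Newick/NEXUS** — trees are carried as verbatim newick strings, never
  re-serialised through a tree object, which makes the round trip exact.
  The NEXUS `Translate` table is applied at label positions (tokens
  following `(` or `,`) when flattening to plain newick; branch lengths
  after `:` are untouched.
* **GFF3/VCF** — native 1-based inclusive coordinates are kept on the
  parsed rows; the shift to BED's 0-based half-open convention happens in
  exactly one place per format (`gff3_to_interval`,
  `variant_to_interval`), so the invariants `bed_start = start − 1` and
  `bed_end − bed_start = reference span` are checked where they are
  produced. GFF3 attributes split on `;`, then `=` (first occurrence),
  with percent-decoding. BED output always has 6 columns — the smallest
  count that carries name, score and strand.
* **SAM** — the 11 mandatory columns are interpreted; optional tags are
  carried verbatim and dropped when exporting reads. Read export skips
  secondary (0x100) and supplementary (0x800) alignments so each read
  appears at most once, and restores sequencing orientation for
  reverse-strand alignments (0x10) by reverse-complementing the sequence
  and reversing the quality string. BAM exists only through the
  external-tool contract (default template
  `samtools view -b -o {output} {input}`, overridable in configuration);
  no native BGZF codec is attempted.

`reverse_complement` maps IUPAC ambiguity codes, preserves case and
passes unknown characters through; it is an involution on DNA alphabets
(U maps to A, so RNA strings intentionally do not round-trip).

`fasta2fastq` must invent qualities; it assigns the constant Phred 40
(`I`) to every base. This is a deliberate, documented placeholder — any
attempt at "realistic" synthetic qualities would suggest information the
file does not contain. The constant is an option (`dummy_quality`).

## Compression

Only gzip and bzip2 are supported; the codec is chosen by the final
filename suffix and verified against the file's magic bytes on read, so a
mislabelled file fails immediately with a codec error instead of deep
inside a parser. Every converter reads and writes through the same
auto-codec opener, which is what makes the 9 in/out codec pairings
byte-equivalent to the plain run (verified converter-by-converter in the
acceptance checks).

## Benchmarking

Single mode runs every method of one converter *N* times (default 5) on
identical inputs, writing outputs to throwaway temporary files so
benchmarking can never clobber user data. Per run it records:

* **wall time** — `time.perf_counter()` (monotonic);
* **CPU time** — user + system of the process tree via `os.times()`,
  including reaped children, so externally shelled-out methods are
  charged fairly. On sub-millisecond conversions this clock's 10 ms
  granularity reports 0; wall time is the measure of record for small
  inputs;
* **peak memory** — the resident set sampled every 50 ms from
  `/proc/self/statm` by a background thread (with an initial sample taken
  immediately, so runs shorter than one interval still yield a value);
  `ru_maxrss` is the non-Linux fallback.

Summary statistics are mean, sample standard deviation (n−1 denominator;
reported as 0 for N = 1), min and max. The error bars are labelled as
standard deviations, not standard errors. Multi mode repeats the whole
single-mode benchmark *M* times (default 10) in-process and sequentially
— no workflow engine — keeping one median wall time per method per
round; the distribution of medians is robust to transient load in a way
a single mean is not. Methods whose external binary is missing are
reported as skipped, and a method that raises is marked failed without
affecting the others. The TSV report is canonical (raw rows plus a
summary block recomputable from them); the bar/box plot is optional.

## Synthetic data

The fixture generator exists so that every converter has deterministic
inputs at any size without shipping data files. A single integer seed
plus the format name and record geometry seed a named pseudorandom
stream (`random.Random` over a string key, which hashes identically on
every platform), so equal specs give byte-identical files. Defaults are
10 records of length 50; benchmark inputs come in size classes of 10²
(small), 10⁴ (medium) and 10⁶ (large) records — the test suite and
acceptance script use small-to-medium sizes, chosen so the full checks
run comfortably on one CPU.

Sequences are uniform random DNA; qualities uniform on [0, 40]
(the realistic printable range for modern instruments); MSA rows carry
~10% gap characters; trees are random binary topologies with uniform
branch lengths; GFF3/VCF features are sorted and non-overlapping; SAM
reads are an even mix of forward and reverse-strand alignments under a
minimal `@HD`/`@SQ` header. None of this models error profiles,
coverage structure, linkage or real annotation nesting — a passing suite
demonstrates format mechanics (parsing, writing, coordinate arithmetic,
round-trip identity), not biological plausibility, and says nothing
about converter behaviour on pathological real-world files beyond the
malformed-input cases tested explicitly.

## CLI conventions

Explicit mode is spelled as a conversion-name first positional
(`biofmt sam2bam test.sam`); when output paths are omitted they are
derived from the first input's base name plus each output format's
canonical (first-registered) extension. Multi-output gates take their
output positionals in the converter's declared port order. Existing
outputs are never overwritten without `-f`. Transitive intermediates
live in a temporary directory, deleted on success and on failure too
unless `--keep-intermediates` asks to keep them for debugging. Every
error path exits nonzero (1 usage/resolution, 2 conversion, 3
environment) with exactly one diagnostic line at default verbosity. A
TOML configuration file can override per-conversion default methods and
external command templates, so deployments can swap backends without
touching code.

## Known limitations

* No BAM/BGZF, FAST5/HDF5 or proteomics formats; BAM is reachable only
  via an external tool.
* PHYLIP interleaved detection is heuristic for files that are both
  ragged and block-ambiguous; strict sequential output sidesteps this on
  the writing side.
* The NEXUS reader handles the TREES block (with Translate) only; DATA
  and CHARACTERS blocks are out of scope.
* Implicit mode cannot express options (wrap width, Phred offset); those
  are library-level arguments.
* Cross-method byte-identity is guaranteed for well-formed input; on
  malformed input different mechanisms may fail at different points
  (though all fail).
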