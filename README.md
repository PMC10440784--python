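# biofmt

Convert life-science files between formats through one command and one
library surface.

Bioinformatics work constantly stumbles over format boundaries: reads in
FASTQ, assemblies in FASTA, alignments in CLUSTAL or PHYLIP or Stockholm,
trees in Newick or NEXUS, annotations in GFF3, variants in VCF, mapped
reads in SAM/BAM — each with its own conventions, and each pair of tools
demanding its own glue script. `biofmt` replaces that glue with a single
converter framework for analysts who would rather not memorise twelve
parsers, and a plugin/benchmark framework for developers who want to add
or compare conversion implementations.

## The model

The core object is a **conversion graph**: nodes are file formats
(registered with their filename extensions and a domain tag), and edges
are converters. A converter from format *A* to *B* is canonically named
`A2B` (`fastq2fasta`); a converter with several input or output ports is
a *logical gate*, named by joining ports with `_`
(`fastq2fasta_qual`, `fasta_qual2fastq`), and appears in the graph as an
anonymous junction node. Each converter exposes one or more named
**methods** — alternative implementations of the same mapping — with a
designated default; methods of one converter must produce byte-identical
output, which is what makes them benchmarkable against each other.

On top of the graph sit four behaviours:

* **implicit mode** — the conversion is inferred from the input and
  output filename extensions (`.fq.gz` → fastq + gzip), so
  `biofmt reads.fastq reads.fasta` needs no further arguments;
* **transitive conversion** — when no direct edge exists, a minimum-hop
  path *A → B → C* is planned over the graph (ties broken by the
  lexicographically smallest intermediate-format sequence) and executed
  through temporary files, with a warning if any hop loses information;
* **transparent compression** — gzip/bzip2 files are decompressed and
  compressed automatically from their extensions, on both sides;
* **benchmarking** — every method of a converter is run *N* times
  (5 by default) on the same input, reporting mean/standard deviation of
  wall time plus CPU time and peak resident memory; a multi-mode variant
  repeats the whole single-mode benchmark *M* times (10 by default) and
  reports the distribution of per-round median run times.

Converters are not registered by hand. A plugin is a plain class whose
`_method_*` callables are discovered automatically, together with its
ports and default method — adding a conversion is a few lines of code.
External tools (e.g. `samtools` for `sam2bam`) plug in through the same
method contract with a configurable command template.

## Worked example

Generate a tiny seeded FASTQ file and convert it:

```
$ python -c 'from biofmt.fixtures import FixtureSpec, generate;
             generate(FixtureSpec("fastq", 3, 24, seed=7), "reads.fastq")'
$ biofmt reads.fastq reads.fasta
biofmt: warning: quality information is lost when converting from FastQ to FastA
```

The warning is the lossiness contract: FASTA has nowhere to put the
Phred scores. To keep them, use the gate — in explicit mode the output
names may be omitted and are derived from the input's base name:

```
$ biofmt -f -v fastq2fasta_qual reads.fastq
biofmt: fastq2fasta_qual (records): 3 record(s) in, 3 out, 0.001s
```

which writes `reads.fasta` and `reads.qual`; merging them back with
`biofmt reads.fasta reads.qual reads.fastq` reproduces the original file
byte for byte. A transitive request routes through the graph:

```
$ biofmt -a reads.fastq reads.phylip
biofmt: warning: transitive route loses information: quality information
is lost when converting from FastQ to FastA
```

Benchmarking the three `fastq2fasta` methods prints the canonical TSV
(one row per method × measure × run, then a summary block):

```
$ biofmt -b -N 3 fastq2fasta reads.fastq
method  measure  run  value
records     wall  1  0.00113442
records     wall  2  0.000770163
records     wall  3  0.000890734
...
#summary  method  measure  mean  std  min  max
```

`records`, `quadruples` and `buffer` are genuinely different mechanisms
(record objects, a four-line state machine, whole-buffer splitting) that
must agree byte-for-byte — the benchmark ranks interchangeable
implementations. `--list`, `--formats`, `--show-methods CONVERSION` and
`--graph` (DOT output for Graphviz) expose the registry itself.

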