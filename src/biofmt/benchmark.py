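"""Benchmarking of competing conversion methods.

Two modes mirror how a conversion method is evaluated in practice:

* **single mode** runs every method of one converter *N* times (5 by
  default) on identical inputs and reports per-run wall-clock time, CPU
  time and peak resident memory, with mean / sample standard deviation /
  min / max per measure;
* **multi mode** repeats the whole single-mode benchmark *M* times
  (10 by default) and keeps one median wall-time per method per round,
  giving a distribution of medians that is robust to transient load.

Wall time uses a monotonic clock; CPU time is user + system of the process
tree (so externally shelled-out methods are charged fairly); memory is the
peak resident set sampled every 50 ms during the run.  Benchmark runs
write their outputs to throwaway files and never touch user outputs.
"""

from __future__ import annotations

import os
import statistics
import tempfile
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

from .converters import convert
from .errors import BenchmarkError, BiofmtError, MissingExecutableError
from .registry import ConverterSpec, Registry

MEASURES = ("wall", "cpu", "memory")

#: resident-set sampling interval, seconds
MEMORY_SAMPLE_INTERVAL = 0.05

_PAGE_SIZE = os.sysconf("SC_PAGE_SIZE")


@dataclass
class BenchmarkConfig:
    """Knobs of a benchmark run.

    ``repeats`` is the single-mode repeat count *N*; ``multi_rounds`` is
    the number of single-mode rounds *M* in multi mode.
    """

    repeats: int = 5
    multi_rounds: int = 10
    include_methods: Sequence[str] | None = None
    measure: tuple[str, ...] = MEASURES

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise BenchmarkError(f"repeats must be >= 1, got {self.repeats}")
        if self.multi_rounds < 1:
            raise BenchmarkError(f"multi_rounds must be >= 1, got {self.multi_rounds}")
        unknown = set(self.measure) - set(MEASURES)
        if unknown:
            raise BenchmarkError(f"unknown measures: {sorted(unknown)}")


@dataclass
class MethodTiming:
    """Raw per-run measurements for one method."""

    method: str
    wall: list[float] = field(default_factory=list)
    cpu: list[float] = field(default_factory=list)
    memory: list[float] = field(default_factory=list)
    failed: str | None = None
    skipped: str | None = None

    def series(self, measure: str) -> list[float]:
        return getattr(self, measure)


@dataclass
class BenchmarkSummary:
    """Single-mode result: N raw measurements per method plus statistics."""

    spec_name: str
    repeats: int
    timings: dict[str, MethodTiming]

    def stats(self, method: str, measure: str) -> dict[str, float]:
        values = self.timings[method].series(measure)
        return {
            "mean": statistics.fmean(values),
            "std": statistics.stdev(values) if len(values) > 1 else 0.0,
            "min": min(values),
            "max": max(values),
        }

    @property
    def measured_methods(self) -> list[str]:
        return [
            m for m, t in self.timings.items() if not t.failed and not t.skipped
        ]


@dataclass
class MultiBenchmarkResult:
    """Multi-mode result: M per-round median wall-times per method."""

    spec_name: str
    rounds: int
    medians: dict[str, list[float]]

    def median_of_medians(self, method: str) -> float:
        return statistics.median(self.medians[method])


class _MemorySampler:
    """Background thread sampling this process's resident set size."""

    def __init__(self, interval: float = MEMORY_SAMPLE_INTERVAL):
        self.interval = interval
        self.peak = 0
        self._stop = threading.Event()
        self._thread = threading.Thread(target=self._run, daemon=True)

    @staticmethod
    def _rss() -> int:
        try:
            with open("/proc/self/statm") as handle:
                return int(handle.read().split()[1]) * _PAGE_SIZE
        except (OSError, IndexError, ValueError):  # non-Linux fallback
            import resource

            return resource.getrusage(resource.RUSAGE_SELF).ru_maxrss * 1024

    def _run(self) -> None:
        while not self._stop.is_set():
            self.peak = max(self.peak, self._rss())
            self._stop.wait(self.interval)

    def __enter__(self) -> "_MemorySampler":
        self.peak = self._rss()
        self._thread.start()
        return self

    def __exit__(self, *exc) -> None:
        self._stop.set()
        self._thread.join()
        self.peak = max(self.peak, self._rss())


def _cpu_seconds() -> float:
    # user + system of self and reaped children
    t = os.times()
    return t.user + t.system + t.children_user + t.children_system


def _throwaway_outputs(registry: Registry, spec: ConverterSpec, directory: str) -> list[str]:
    return [
        str(Path(directory) / f"bench_{i}{registry.get_format(fmt).primary_extension}")
        for i, fmt in enumerate(spec.outputs)
    ]


def _selected_methods(spec: ConverterSpec, config: BenchmarkConfig) -> list[str]:
    methods = list(spec.methods)
    if config.include_methods is not None:
        include = set(config.include_methods)
        methods = [m for m in methods if m in include]
    if not methods:
        raise BenchmarkError(
            f"no methods of {spec.name!r} selected for benchmarking"
        )
    return methods


def run_single(
    registry: Registry,
    spec: ConverterSpec | str,
    inputs: list[str],
    config: BenchmarkConfig | None = None,
    options: dict | None = None,
) -> BenchmarkSummary:
    """Run every selected method ``config.repeats`` times on ``inputs``.

    Methods whose external binary is absent are marked skipped; a method
    raising a conversion error is marked failed with the error text.
    Other methods are unaffected either way.
    """
    if isinstance(spec, str):
        spec = registry.get_converter(spec)
    config = config or BenchmarkConfig()
    timings: dict[str, MethodTiming] = {}
    with tempfile.TemporaryDirectory(prefix="biofmt_bench_") as tmp:
        for method in _selected_methods(spec, config):
            timing = MethodTiming(method)
            timings[method] = timing
            outputs = _throwaway_outputs(registry, spec, tmp)
            for _ in range(config.repeats):
                try:
                    wall0 = time.perf_counter()
                    cpu0 = _cpu_seconds()
                    with _MemorySampler() as sampler:
                        convert(
                            registry, spec, inputs, outputs,
                            method=method, options=options,
                        )
                    timing.wall.append(time.perf_counter() - wall0)
                    timing.cpu.append(_cpu_seconds() - cpu0)
                    timing.memory.append(float(sampler.peak))
                except MissingExecutableError as exc:
                    timing.skipped = str(exc)
                    timing.wall.clear(), timing.cpu.clear(), timing.memory.clear()
                    break
                except BiofmtError as exc:
                    timing.failed = str(exc)
                    timing.wall.clear(), timing.cpu.clear(), timing.memory.clear()
                    break
    return BenchmarkSummary(spec.name, config.repeats, timings)


def run_multi(
    registry: Registry,
    spec: ConverterSpec | str,
    inputs: list[str],
    config: BenchmarkConfig | None = None,
    options: dict | None = None,
) -> MultiBenchmarkResult:
    """Repeat the single-mode benchmark ``config.multi_rounds`` times,
    keeping one median wall-time per method per round."""
    if isinstance(spec, str):
        spec = registry.get_converter(spec)
    config = config or BenchmarkConfig()
    medians: dict[str, list[float]] = {}
    for _ in range(config.multi_rounds):
        summary = run_single(registry, spec, inputs, config, options=options)
        for method in summary.measured_methods:
            medians.setdefault(method, []).append(
                statistics.median(summary.timings[method].wall)
            )
    if not medians:
        raise BenchmarkError(f"no method of {spec.name!r} produced measurements")
    return MultiBenchmarkResult(spec.name, config.multi_rounds, medians)


def report(
    result: BenchmarkSummary | MultiBenchmarkResult,
    sink: IO[str],
    as_image: bool = False,
    image_path: str | None = None,
) -> None:
    """Write the canonical TSV report; optionally render a plot.

    Single-mode TSV: one row per (method, measure, run) plus a summary
    block with mean/std/min/max.  Multi-mode TSV: one row per (method,
    round) median.  The plot is a bar-with-error chart (single) or a box
    plot of medians per method (multi).
    """
    if isinstance(result, BenchmarkSummary):
        sink.write("method\tmeasure\trun\tvalue\n")
        for method, timing in result.timings.items():
            if timing.failed or timing.skipped:
                continue
            for measure in MEASURES:
                for run, value in enumerate(timing.series(measure), start=1):
                    sink.write(f"{method}\t{measure}\t{run}\t{value:.9g}\n")
        sink.write("#summary\tmethod\tmeasure\tmean\tstd\tmin\tmax\n")
        for method in result.measured_methods:
            for measure in MEASURES:
                s = result.stats(method, measure)
                sink.write(
                    f"#summary\t{method}\t{measure}\t{s['mean']:.9g}\t{s['std']:.9g}"
                    f"\t{s['min']:.9g}\t{s['max']:.9g}\n"
                )
        for method, timing in result.timings.items():
            if timing.skipped:
                sink.write(f"#skipped\t{method}\t{timing.skipped}\n")
            if timing.failed:
                sink.write(f"#failed\t{method}\t{timing.failed}\n")
    else:
        sink.write("method\tmeasure\tround\tvalue\n")
        for method, values in result.medians.items():
            for round_index, value in enumerate(values, start=1):
                sink.write(f"{method}\tmedian_wall\t{round_index}\t{value:.9g}\n")
    if as_image:
        _plot(result, image_path or "benchmark.png")


def _plot(result: BenchmarkSummary | MultiBenchmarkResult, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if isinstance(result, BenchmarkSummary):
        methods = result.measured_methods
        means = [result.stats(m, "wall")["mean"] for m in methods]
        stds = [result.stats(m, "wall")["std"] for m in methods]
        ax.bar(methods, means, yerr=stds, capsize=4, color="steelblue")
        ax.set_ylabel("wall time (s), mean of %d runs" % result.repeats)
        ax.set_title(f"{result.spec_name}: single-mode benchmark")
    else:
        methods = list(result.medians)
        ax.boxplot([result.medians[m] for m in methods], tick_labels=methods)
        ax.set_ylabel("median wall time per round (s)")
        ax.set_title(f"{result.spec_name}: multi-mode benchmark ({result.rounds} rounds)")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
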