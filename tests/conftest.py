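import random

import pytest

from biofmt import default_registry
from biofmt.fixtures import FixtureSpec, generate
from biofmt.registry import ConverterSpec, FormatDescriptor, Registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def make_fixture(tmp_path):
    """Generate a seeded synthetic file of a given format in tmp_path."""

    def _make(format, n_records=10, record_length=50, seed=0, name=None, compression=None):
        ext = {"gff3": ".gff", "stockholm": ".sto", "newick": ".nwk"}.get(
            format, f".{format}"
        )
        filename = name or f"fixture_{format}_{seed}{ext}"
        spec = FixtureSpec(format, n_records, record_length, seed, compression)
        return generate(spec, tmp_path / filename)

    return _make


def make_linear_registry(edges, lossy=frozenset(), nodes=()):
    """A registry over token formats with the given (src, dst) edges."""
    registry = Registry()
    names = sorted({n for e in edges for n in e} | set(nodes))
    for name in names:
        registry.register_format(FormatDescriptor(name, (f".{name}",), "other"))
    for src, dst in edges:
        registry.register_converter(
            ConverterSpec(
                inputs=(src,), outputs=(dst,), methods=("m",), default_method="m",
                lossy=(src, dst) in lossy,
            )
        )
    return registry


def random_edge_set(rng: random.Random, n_nodes: int, n_edges: int):
    """Random distinct directed edges (no self-loops) over fN node names."""
    nodes = [f"f{i}" for i in range(n_nodes)]
    candidates = [(a, b) for a in nodes for b in nodes if a != b]
    rng.shuffle(candidates)
    return nodes, candidates[:n_edges]


def brute_force_shortest(edges, source, target):
    """Exhaustive simple-path enumeration; min by (hops, intermediate names).

    Returns the node sequence of the optimal path (source..target), or None
    when target is unreachable.  Independent of the registry's search.
    """
    adjacency = {}
    for a, b in edges:
        adjacency.setdefault(a, set()).add(b)
    best = None

    def visit(node, path):
        nonlocal best
        if node == target:
            key = (len(path) - 1, tuple(path[1:]))
            if best is None or key < best:
                best = key
            return
        for nxt in sorted(adjacency.get(node, ())):
            if nxt not in path:
                visit(nxt, path + [nxt])

    visit(source, [source])
    if best is None:
        return None
    return (source,) + best[1]
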