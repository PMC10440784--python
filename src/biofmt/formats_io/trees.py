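"""Phylogenetic tree formats: Newick and NEXUS (TREES block).

Trees are carried as verbatim newick strings rather than decomposed tree
objects: conversion between these two formats is a container change, and
keeping the newick text untouched guarantees lossless round trips.  The
NEXUS ``Translate`` table is the one transformation applied: shorthand
tokens are substituted by taxon names when a document is flattened to
plain newick.
"""

from __future__ import annotations

import re
from typing import IO, Iterator

from ..errors import ParseError
from .records import TreeDocument

_TOKEN = re.compile(r"([(),;:])")


def parse_newick(source: IO[str], metadata: dict | None = None) -> Iterator[TreeDocument]:
    """Parse one or more ';'-terminated newick trees into a TreeDocument."""
    trees: list[tuple[str, str]] = []
    buffer: list[str] = []
    lineno = 0
    for line in source:
        lineno += 1
        text = line.strip()
        if not text:
            continue
        buffer.append(text)
        while ";" in buffer[-1]:
            joined = "".join(buffer)
            newick, _, rest = joined.partition(";")
            newick = newick.strip() + ";"
            if newick.count("(") != newick.count(")"):
                raise ParseError(
                    f"unbalanced parentheses in tree ending", line=lineno
                )
            trees.append((f"TREE{len(trees) + 1}", newick))
            buffer = [rest.strip()] if rest.strip() else []
            if not buffer:
                break
    if buffer:
        raise ParseError("trailing tree text without terminating ';'", line=lineno)
    if not trees:
        raise ParseError("no trees found in newick input")
    yield TreeDocument(trees).validate()


def write_newick(documents, sink: IO[str]) -> int:
    """Write one newick string per line, applying any Translate table."""
    count = 0
    for doc in _iter_documents(documents):
        doc.validate()
        for _, newick in doc.trees:
            sink.write(apply_translate(newick, doc.translate) + "\n")
            count += 1
    return count


def apply_translate(newick: str, translate: dict[str, str]) -> str:
    """Substitute taxon tokens through a NEXUS Translate table.

    Only label positions are touched: tokens directly following ``(`` or
    ``,`` (branch lengths after ``:`` and structural characters are left
    alone).
    """
    if not translate:
        return newick
    pieces = _TOKEN.split(newick)
    out: list[str] = []
    previous = "("  # a leading token is a label
    for piece in pieces:
        if piece in "(),;:":
            out.append(piece)
            previous = piece
        else:
            token = piece.strip()
            if token and previous in "(,":
                out.append(piece.replace(token, translate.get(token, token)))
            else:
                out.append(piece)
            if token:
                previous = ""
    return "".join(out)


def parse_nexus(source: IO[str], metadata: dict | None = None) -> Iterator[TreeDocument]:
    """Parse the TREES block of a NEXUS file (trees plus Translate table)."""
    first = source.readline()
    if not first.strip().upper().startswith("#NEXUS"):
        raise ParseError(f"missing #NEXUS header, got {first.strip()!r}", line=1)
    text = source.read()
    block = re.search(r"begin\s+trees\s*;(.*?)end\s*;", text, re.IGNORECASE | re.DOTALL)
    if not block:
        raise ParseError("no TREES block found in NEXUS input")
    body = block.group(1)
    translate: dict[str, str] = {}
    tmatch = re.search(r"translate\s+(.*?);", body, re.IGNORECASE | re.DOTALL)
    if tmatch:
        for entry in tmatch.group(1).split(","):
            parts = entry.split()
            if len(parts) == 2:
                translate[parts[0]] = parts[1]
    trees: list[tuple[str, str]] = []
    for match in re.finditer(
        r"tree\s+(\S+)\s*=\s*(?:\[[^\]]*\]\s*)?([^;]+);", body, re.IGNORECASE
    ):
        label = match.group(1)
        newick = match.group(2).strip() + ";"
        if newick.count("(") != newick.count(")"):
            raise ParseError(f"unbalanced parentheses in tree {label!r}")
        trees.append((label, newick))
    if not trees:
        raise ParseError("NEXUS TREES block contains no tree statements")
    yield TreeDocument(trees, translate).validate()


def write_nexus(documents, sink: IO[str]) -> int:
    """Wrap each tree as ``tree <label> = <newick>`` inside a TREES block."""
    count = 0
    for doc in _iter_documents(documents):
        doc.validate()
        sink.write("#NEXUS\nbegin trees;\n")
        for i, (label, newick) in enumerate(doc.trees, start=1):
            name = label or f"TREE{i}"
            sink.write(f"  tree {name} = {apply_translate(newick, doc.translate)}\n")
        sink.write("end;\n")
        count += len(doc.trees)
    return count


def _iter_documents(documents) -> Iterator[TreeDocument]:
    if isinstance(documents, TreeDocument):
        yield documents
    else:
        for item in documents:
            if not isinstance(item, TreeDocument):
                raise ParseError(
                    f"tree writers take TreeDocument objects, got {type(item).__name__}"
                )
            yield item
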