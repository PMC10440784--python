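"""Transparent compressed text I/O keyed on filename extension.

A ``.gz`` or ``.bz2`` suffix selects the codec; anything else opens as a
plain text file.  Downstream parsers and writers are codec-agnostic: they
always see a text stream.  On read, the file's magic bytes are checked
against the codec the extension promises, so a mislabelled file fails
immediately with a :class:`~biofmt.errors.CodecError` rather than deep in
a parser.
"""

from __future__ import annotations

import bz2
import gzip
from pathlib import Path
from typing import IO

from .errors import CodecError

#: magic byte prefixes per codec
_MAGIC = {"gzip": b"\x1f\x8b", "bzip2": b"BZh"}

_SUFFIX_CODEC = {".gz": "gzip", ".bz2": "bzip2"}


def codec_for(path: str) -> str | None:
    """Return the codec implied by the final filename suffix, if any."""
    return _SUFFIX_CODEC.get(Path(str(path)).suffix.lower())


def open_auto(path: str, mode: str = "r", encoding: str = "utf-8") -> IO[str]:
    """Open ``path`` for text I/O, (de)compressing according to its extension.

    ``mode`` is ``"r"`` or ``"w"`` (text). In read mode the magic bytes are
    verified against the extension's codec first.
    """
    if mode not in {"r", "w"}:
        raise ValueError(f"mode must be 'r' or 'w', got {mode!r}")
    codec = codec_for(path)
    if codec is None:
        return open(path, mode, encoding=encoding)
    if mode == "r":
        _check_magic(path, codec)
    opener = gzip.open if codec == "gzip" else bz2.open
    return opener(path, mode + "t", encoding=encoding)


def _check_magic(path: str, codec: str) -> None:
    magic = _MAGIC[codec]
    with open(path, "rb") as handle:
        head = handle.read(len(magic))
    if head != magic:
        raise CodecError(
            f"{path}: extension promises {codec} but the content is not "
            f"{codec}-compressed"
        )
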