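"""Exception hierarchy.

Every error raised by biofmt derives from :class:`BiofmtError`, so callers
(notably the CLI) can map failures onto exit codes without matching on
message text.
"""

from __future__ import annotations


class BiofmtError(Exception):
    """Base class for all biofmt errors."""


class RegistryError(BiofmtError):
    """Problems with format/converter registration or lookup."""


class RegistrationError(RegistryError):
    """A format or converter violates a registration invariant."""


class ExtensionConflictError(RegistryError):
    """Two formats claim the same filename extension."""


class UnresolvableExtensionError(RegistryError):
    """A filename extension maps to no registered format."""


class NoConverterError(RegistryError):
    """No registered converter matches the requested input/output formats."""


class NoPathError(RegistryError):
    """No transitive conversion path connects two formats."""


class InvalidConverterError(RegistryError):
    """A converter plugin does not satisfy the plugin contract."""


class UnknownMethodError(BiofmtError):
    """A method name is not offered by the converter."""

    def __init__(self, method: str, available: tuple[str, ...]):
        super().__init__(
            f"unknown method {method!r}; available methods: {', '.join(available)}"
        )
        self.method = method
        self.available = available


class ParseError(BiofmtError):
    """Malformed input text; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class EncodingError(BiofmtError):
    """Quality-string characters incompatible with the Phred offset."""


class PairingError(BiofmtError):
    """Mismatched records between paired input files (e.g. FASTA + QUAL)."""


class CoordinateError(BiofmtError):
    """Genomic coordinates violate their format's convention."""


class CodecError(BiofmtError):
    """File content does not match the codec its extension promises."""


class ConversionError(BiofmtError):
    """A conversion failed for reasons other than the environment."""


class EnvironmentError_(BiofmtError):
    """The host environment lacks something a conversion needs."""


class MissingExecutableError(EnvironmentError_):
    """An external method's executable is absent from PATH."""

    def __init__(self, executable: str):
        super().__init__(f"required external executable not found on PATH: {executable!r}")
        self.executable = executable


class ExternalToolError(EnvironmentError_):
    """An external tool exited with a nonzero status."""

    def __init__(self, command: str, returncode: int, stderr: str):
        super().__init__(
            f"external command failed with exit status {returncode}: {command}\n{stderr.strip()}"
        )
        self.command = command
        self.returncode = returncode
        self.stderr = stderr


class BenchmarkError(BiofmtError):
    """Invalid benchmark configuration or a wholly failed benchmark."""
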