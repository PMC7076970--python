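"""Exception hierarchy.

Every error raised by the library derives from :class:`EnrichKitError` so the
command-line layer can map failures onto its exit-code contract
(2 usage, 3 input validation, 4 build failure).
"""

from __future__ import annotations


class EnrichKitError(Exception):
    """Base class for all enrichkit errors."""

    exit_code: int = 3


class ParseError(EnrichKitError):
    """A file could not be parsed; the message names the offending line."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class OboParseError(ParseError):
    """Malformed OBO stanza, dangling parent reference, or cycle."""


class UnknownTermError(EnrichKitError):
    """A term id does not resolve to any term in the ontology."""


class ObsoleteTermError(EnrichKitError):
    """A term id resolves to an obsolete term where a live one is required."""


class ValidationError(EnrichKitError):
    """Invalid user input (counts out of bounds, empty query, bad flag)."""


class BuildError(EnrichKitError):
    """Library construction failed (missing inputs, zero surviving rows)."""

    exit_code = 4


class LibraryFormatError(EnrichKitError):
    """An on-disk library file does not carry the expected format marker."""
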