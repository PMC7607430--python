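"""Exception hierarchy and machine-readable diagnostics."""

from __future__ import annotations

from dataclasses import dataclass


class LicorrError(Exception):
    """Base class for all licorr errors."""


class RegistryError(LicorrError):
    """Unknown or conflicting monosaccharide/modification code."""


class ParseError(LicorrError):
    """A glycan, pattern, or constraint string failed to parse.

    Carries a 0-based character ``offset`` into the offending input and a
    short machine-readable ``code``.
    """

    def __init__(self, message: str, offset: int = 0, code: str = "E_PARSE"):
        super().__init__(f"{message} (offset {offset})")
        self.message = message
        self.offset = offset
        self.code = code


class UnsupportedFeatureError(LicorrError):
    """A notation is recognized but its semantics are deliberately not
    implemented (e.g. expansion of cyclic repeats)."""


class RuleError(LicorrError):
    """Ill-formed reaction rule (e.g. substrate/product wildcard mismatch)."""


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: an error or a warning, never raised."""

    code: str
    offset: int
    message: str
    severity: str = "error"  # "error" | "warning"

    def as_tsv(self) -> str:
        return f"{self.code}\t{self.offset}\t{self.message}"
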