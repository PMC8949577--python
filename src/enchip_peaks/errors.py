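"""Exception hierarchy shared across the package.

Usage errors (bad invocation, malformed criterion strings, missing base
file) map to CLI exit code 1; data/format errors (unparseable peak files,
unresolvable target locus) map to exit code 2.
"""


class EnchipError(Exception):
    """Base class for all package errors."""


class UsageError(EnchipError):
    """The operation was invoked incorrectly (wrong arity, bad grammar)."""


class PeakFormatError(EnchipError):
    """A peak file violates the expected tab-file dialect."""

    def __init__(self, message: str, path: str | None = None,
                 line_number: int | None = None):
        self.path = path
        self.line_number = line_number
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line_number is not None:
            prefix += f"line {line_number}: "
        super().__init__(prefix + message)


class TargetLocusError(EnchipError):
    """No peak in the list overlaps the configured target locus."""


class GenerationError(EnchipError):
    """Synthetic-experiment generation is infeasible for the parameters."""
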