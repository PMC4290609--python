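"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes so that batch callers can tell a
malformed file from an inconsistent sample design or a bad argument.
"""


class PcafeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PcafeError):
    """A file does not conform to the expected dialect (missing delimiters,
    malformed rows, wrong column counts). Carries the offending line number
    where one is known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DesignError(PcafeError):
    """A sample is missing from the design table, or a design category that
    the analysis requires is empty."""
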