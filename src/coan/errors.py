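"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (usage 2, parse 3, numeric 4).
"""


class CoanError(Exception):
    """Base class for all package-specific errors."""


class UsageError(CoanError):
    """Invalid parameter or option combination."""


class ParseError(CoanError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f"{path}"
            if line is not None:
                where += f":{line}"
            where += ": "
        super().__init__(where + message)


class NumericError(CoanError):
    """Numerical failure (singular system, non-convergence)."""
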