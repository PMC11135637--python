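"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: config errors -> 2, parse/structure
errors -> 3, evaluation errors -> 4.
"""


class TaxvoteError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TaxvoteError):
    """Invalid configuration: weights, strategy, simulation parameters."""


class ParseError(TaxvoteError):
    """Malformed input file.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno


class StructureError(ParseError):
    """Taxonomy violates tree invariants (cycle, dangling parent, no root)."""


class UnknownTaxidError(TaxvoteError, KeyError):
    """A taxid was queried that is not present in the taxonomy."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep message plain
        return Exception.__str__(self)


class EvaluationError(TaxvoteError):
    """Assignments and truth are inconsistent at scoring time."""
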