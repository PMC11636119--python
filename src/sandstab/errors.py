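"""Exception hierarchy shared across the package.

Everything derives from :class:`SandstabError` so callers can catch one
base class; the subclasses distinguish schema problems in input tables,
referential problems between tables, degenerate numerical inputs, and
curve-fitting failures.
"""


class SandstabError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SandstabError):
    """A required column is missing or an unknown variable was requested."""


class RowError(SandstabError):
    """A cell in a data row failed to parse or violates a field bound.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ReferentialError(SandstabError):
    """An observation references a quadrat that does not exist."""


class NotFoundError(SandstabError):
    """A requested stratum (restoration year / position) is absent."""


class DegenerateInputError(SandstabError):
    """An input is structurally valid but numerically degenerate
    (e.g. a stratum whose total coverage is zero)."""


class FitError(SandstabError):
    """Curve fitting failed: too few points or a singular design."""


class NoIntersectionError(SandstabError):
    """The fitted curve does not cross the anti-diagonal in [0, 100]."""


class InconsistencyError(SandstabError):
    """Derived quantities violate a mathematical identity beyond tolerance
    (e.g. Shannon diversity exceeding ln S)."""


class ConfigError(SandstabError):
    """A synthetic-data configuration violates its invariants."""
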