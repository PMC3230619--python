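"""Exception hierarchy.

All package errors derive from :class:`BioturbError` so callers (and the
command-line interface) can distinguish misuse, bad input files and internal
consistency failures.
"""


class BioturbError(Exception):
    """Base class for all errors raised by bioturb."""


class ConfigurationError(BioturbError, ValueError):
    """A parameter or configuration value violates its invariants."""


class ConsistencyError(BioturbError, RuntimeError):
    """An internal mass-balance or bookkeeping invariant was violated.

    Raised when a displacement ledger removes more tracer than a layer
    holds, or when a lattice enters passive rebalancing with the wrong
    total particle count — both indicate a bug upstream, not user error.
    """


class NumericalError(BioturbError, RuntimeError):
    """A numerical procedure failed (non-finite objective, degenerate data)."""


class ShapeError(BioturbError, ValueError):
    """Observed and simulated matrices have incompatible dimensions."""


class ProfileParseError(BioturbError, ValueError):
    """A profile file contained a cell that could not be parsed.

    Attributes
    ----------
    row, column : int or None
        1-based location of the offending cell, when known.
    """

    def __init__(self, message: str, row: int | None = None, column: int | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class ProfileFormatError(BioturbError, ValueError):
    """A profile file is structurally malformed (e.g. ragged rows)."""
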