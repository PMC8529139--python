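"""Exception hierarchy for dtameta.

All data-facing errors derive from :class:`DtaMetaError` so callers can
catch the package's failures with a single except clause; numerical
problems during model fitting raise :class:`ConvergenceError`.
"""


class DtaMetaError(Exception):
    """Base class for all dtameta errors."""


class FormatError(DtaMetaError, ValueError):
    """An input table is structurally malformed (e.g. a missing column)."""


class ValidationError(DtaMetaError, ValueError):
    """A study table violates a content invariant (counts, duplicate ids)."""


class FixtureNotFoundError(DtaMetaError, LookupError):
    """Requested packaged dataset does not exist."""


class InsufficientStudiesError(DtaMetaError, ValueError):
    """Too few trials for the requested analysis."""


class ConvergenceError(DtaMetaError, RuntimeError):
    """Optimizer failed to converge; carries the best point found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class DegenerateGeometryError(DtaMetaError, ValueError):
    """A fit has zero between-study variance on an axis needed for the SROC."""
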