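"""Typed exceptions raised by niptkit.

All domain errors derive from :class:`NiptError` so callers (notably the
CLI) can map them to a single exit code while still catching specific
failure modes in tests.
"""


class NiptError(Exception):
    """Base class for all niptkit domain errors."""


class MalformedFilenameError(NiptError):
    """Run filename does not start with a valid YYMMDD date."""


class SchemaError(NiptError):
    """Run CSV is structurally invalid (missing column, capacity exceeded)."""


class CellValueError(NiptError, ValueError):
    """A single CSV cell could not be parsed; message names row and column."""


class DuplicateSampleError(NiptError):
    """Two rows in one run share a sample id."""


class EmptyRunError(NiptError):
    """Run CSV contains a header but zero sample rows."""


class DuplicateRunError(NiptError):
    """A run with the same source filename is already stored."""


class InsufficientCalibrationDataError(NiptError):
    """Too few samples in a calibration subset; message names the subset."""


class InfeasibleDesignError(NiptError):
    """A cohort specification cannot be packed into the requested runs."""


class MissingInterpretationError(NiptError):
    """A report was requested for samples lacking interpretations."""


class DegenerateFitWarning(UserWarning):
    """Regression residuals collapsed to ~0; residual SD floored."""
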