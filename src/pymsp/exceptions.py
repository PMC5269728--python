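"""Exception hierarchy for the pipeline.

Estimation-level problems (a cell that cannot be fitted) are represented by
:class:`EstimationError` subclasses so callers can record them against the
offending record instead of aborting a run.
"""


class PyMSPError(Exception):
    """Base class for all package errors."""


class DomainError(PyMSPError, ValueError):
    """An argument lies outside the mathematically supported range."""


class FormatError(PyMSPError, ValueError):
    """Input data violate the expected file/grid format."""


class EstimationError(PyMSPError, RuntimeError):
    """A per-record estimation step failed; recoverable at pipeline level."""


class DegenerateSpectrumError(EstimationError):
    """Spectrum has no usable signal (peak does not exceed baseline)."""


class InsufficientLimbError(EstimationError):
    """Too few eligible samples on the required limb of the spectrum."""


class AmbiguousSpectrumError(EstimationError):
    """The cut-off construction found zero or multiple half-maximum crossings."""


class ContractViolation(PyMSPError, ValueError):
    """A caller violated an operation precondition."""
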