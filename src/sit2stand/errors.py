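"""Exception hierarchy shared across the pipeline.

Each stage raises a specific subclass so the CLI can map failures to
stable exit codes (input/schema -> 2, degenerate data -> 3, numerics -> 4).
"""


class Sit2StandError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(Sit2StandError, ValueError):
    """An argument violates a precondition (non-finite, wrong shape, ...)."""


class SchemaError(Sit2StandError):
    """An input file is missing required columns or is unreadable."""


class DegenerateDataError(Sit2StandError):
    """The data cannot support the operation (e.g. no transitions found)."""


class InsufficientDataError(DegenerateDataError):
    """Too few observations for the requested statistic or clustering."""


class StructuralError(Sit2StandError):
    """Episode structure violates the alternating state-machine contract."""


class NumericalError(Sit2StandError):
    """A numerical failure (singular innovation covariance, ...)."""
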