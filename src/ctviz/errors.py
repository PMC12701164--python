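"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: validation errors exit 2, I/O and
format errors exit 3, resource/budget errors exit 4.
"""


class CtvizError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(CtvizError):
    """Invalid parameters, inconsistent metadata or malformed requests."""

    exit_code = 2


class VolumeIOError(CtvizError):
    """Missing, unreadable or structurally invalid input/output files."""

    exit_code = 3


class FormatError(VolumeIOError):
    """A file parsed but did not conform to the expected layout."""


class BudgetError(CtvizError):
    """A resource budget (texture size, upload memory) cannot be satisfied."""

    exit_code = 4
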