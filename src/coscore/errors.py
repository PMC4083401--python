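"""Exception hierarchy shared across the pipeline.

Validation errors (bad parameters, malformed config) exit the CLI with code 2;
data errors (inputs that cannot be analysed) exit with code 3.
"""


class CoscoreError(Exception):
    """Base class for all package errors."""


class ValidationError(CoscoreError):
    """A parameter or configuration value is out of range or malformed."""

    exit_code = 2


class DataError(CoscoreError):
    """Input data cannot be analysed (missing columns, no overlap, ...)."""

    exit_code = 3


class DegenerateInputError(DataError):
    """A feature cannot be dichotomized (constant vector, too few samples)."""


class TieError(DegenerateInputError):
    """Two clusters have equal medians; UP/DOWN labels are undefined."""


class UnscorableError(DataError):
    """A survival comparison cannot be made (empty group, zero exposure)."""
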