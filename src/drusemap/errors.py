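"""Exception hierarchy shared across the pipeline.

Validation errors map to CLI exit code 2, numeric/algorithmic failures
to exit code 3.
"""


class DrusemapError(Exception):
    """Base class for all package errors."""


class ValidationError(DrusemapError, ValueError):
    """Malformed or contract-violating input (CLI exit 2)."""


class DegenerateGeometryError(ValidationError):
    """Landmark geometry insufficient to determine the transform."""


class NumericError(DrusemapError, RuntimeError):
    """Numerical/algorithmic failure during analysis (CLI exit 3)."""
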