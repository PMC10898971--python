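"""Exception hierarchy shared across the package."""


class FlukemrError(Exception):
    """Base class for all package errors."""


class ValidationError(FlukemrError, ValueError):
    """Invalid input data or configuration (CLI exit code 2)."""


class EstimationError(FlukemrError, RuntimeError):
    """Estimation could not be completed (CLI exit code 3)."""
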