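"""Exception hierarchy shared across gonodyn modules."""


class GonodynError(Exception):
    """Base class for all gonodyn errors."""


class ValidationError(GonodynError, ValueError):
    """Invalid input data or configuration (CLI exit code 1)."""


class PipelineError(GonodynError, RuntimeError):
    """Failure while executing an analysis stage (CLI exit code 2)."""
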