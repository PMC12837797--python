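"""Exception hierarchy for the pipeline.

All pipeline errors derive from :class:`PipelineError` (itself a
``ValueError``) so callers can catch broadly or by category.
"""


class PipelineError(ValueError):
    """Base class for all errors raised by lumbarload."""


class InputError(PipelineError):
    """Malformed or inconsistent input data (missing markers, empty traces,
    mismatched channels or timebases)."""


class ParameterError(PipelineError):
    """Invalid processing parameter (even RMS window, non-positive rate)."""


class ConfigurationError(PipelineError):
    """Invalid or incomplete configuration (unknown contraction speed,
    missing relationship or coefficient-table entry)."""


class GeometryError(PipelineError):
    """Physically degenerate muscle geometry (non-positive moment arm,
    moment arm exceeding the lever arm, cos of the line-of-action angle = 0)."""


class FitError(PipelineError):
    """Regression cannot be performed (too few samples, zero envelope
    variance, non-positive envelopes for a logarithmic fit)."""
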