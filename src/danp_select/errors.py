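"""Exception hierarchy shared by all modules."""


class DanpError(Exception):
    """Base class for all package errors."""


class SchemaError(DanpError):
    """Invalid decision-network document (duplicate labels, dangling block, ...)."""


class AggregationError(DanpError):
    """Participant judgment sets cannot be merged (context/dimension mismatch)."""


class ValidationError(DanpError):
    """A judgment matrix violates its structural contract."""


class DegenerateInputError(DanpError):
    """Input is structurally valid but numerically degenerate (all-zero matrix, zero column)."""


class NonConvergenceError(DanpError):
    """An iterative or series computation does not converge."""


class PipelineError(DanpError):
    """A pipeline run cannot proceed (missing matrix, strict consistency gate, ...)."""
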