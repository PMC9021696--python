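"""Exception hierarchy used across the pipeline."""


class RcspeError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(RcspeError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(RcspeError, ValueError):
    """Input is formally valid but numerically degenerate (rank loss, zero variance)."""


class ConvergenceError(RcspeError, RuntimeError):
    """An iterative decomposition failed to converge after all restarts."""


class SchemaError(RcspeError, KeyError):
    """A session container is missing required groups or datasets."""
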