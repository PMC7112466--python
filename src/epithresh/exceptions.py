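"""Exception hierarchy shared across the package."""


class EpithreshError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(EpithreshError, ValueError):
    """A parameter violates a precondition (e.g. beta = lambda * mu > 1)."""


class GenerationError(EpithreshError, RuntimeError):
    """A random-graph construction failed within its retry budget."""


class EdgeListParseError(EpithreshError, ValueError):
    """An edge-list file contains a malformed line."""

    def __init__(self, path, line_number, message):
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class DegenerateGraphError(EpithreshError, ValueError):
    """The degree sequence does not admit the requested threshold formula."""


class NoFiniteThresholdError(DegenerateGraphError):
    """The closed-form threshold denominator is non-positive."""


class NumericalError(EpithreshError, RuntimeError):
    """An iterative numerical routine failed to converge."""
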