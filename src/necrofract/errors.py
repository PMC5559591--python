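"""Exception hierarchy shared across the package."""


class NecrofractError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NecrofractError, ValueError):
    """An argument violates a documented precondition."""


class DegeneratePhantomError(NecrofractError):
    """A phantom came out unusable (e.g. necrosis emptied by hole punching)."""


class EmptyRegionError(NecrofractError):
    """A mask submitted to fractal analysis has no foreground."""


class ProtocolError(NecrofractError):
    """A scan protocol cannot be realised on the given mask."""


class InsufficientScalingError(NecrofractError):
    """Fewer than two usable box sizes; no slope can be fitted."""


class GraphError(NecrofractError):
    """The affinity graph or its seeding is invalid."""


class ConvergenceError(NecrofractError):
    """An iterative fit failed to reach its tolerance."""


class AlignmentError(NecrofractError):
    """Patient identifiers do not line up between two tables."""


class UndefinedCorrelationError(NecrofractError):
    """Pearson correlation requested on a zero-variance vector."""
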