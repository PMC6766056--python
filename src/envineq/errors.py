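"""Exception hierarchy shared across the package."""


class EnvineqError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EnvineqError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class SchemaError(EnvineqError, ValueError):
    """An input table is missing columns or violates its documented schema."""


class QuintileError(EnvineqError, ValueError):
    """Income quintiles are undefined (too few areas or degenerate values)."""


class GraphError(EnvineqError, ValueError):
    """The areal adjacency graph does not satisfy a structural requirement."""


class InsufficientDataError(EnvineqError, ValueError):
    """Too few observations to fit the requested model."""


class FitFailureError(EnvineqError, RuntimeError):
    """Numerical optimisation failed to produce a finite optimum."""


class ConvergenceError(EnvineqError, RuntimeError):
    """Strict mode: the fit did not meet its convergence criteria."""


class AlignmentError(EnvineqError, ValueError):
    """Two tables that must share an (area, year) index do not."""


class PartialCoverageError(EnvineqError, ValueError):
    """Noise bands fail to cover some areal units to tolerance."""

    def __init__(self, message, offending_areas=()):
        super().__init__(message)
        self.offending_areas = list(offending_areas)


class SimulationParameterError(EnvineqError, ValueError):
    """Simulation parameters produce unusable (e.g. overflowing) intensities."""


class PoolingError(EnvineqError, ValueError):
    """Posterior pooling requested over incompatible fits."""


class FormatError(EnvineqError, ValueError):
    """A serialized artifact violates its documented on-disk format."""
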