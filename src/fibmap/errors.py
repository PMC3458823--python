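"""Exception hierarchy for the mapping pipeline."""


class FibmapError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(FibmapError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateGeometryError(FibmapError):
    """Electrode layout cannot support planar interpolation (e.g. collinear)."""


class SimulationFailureError(FibmapError):
    """Tissue simulation produced non-finite state.

    Carries the time step index at which the instability was detected.
    """

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite tissue state at step {step}")


class InsufficientDataError(FibmapError):
    """Too few active channels / samples to build the requested map."""


class ConfigError(FibmapError, ValueError):
    """Run configuration is invalid; the message names the offending key."""
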