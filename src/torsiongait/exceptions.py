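"""Exception hierarchy used across the package."""


class TorsionGaitError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(TorsionGaitError):
    """Degenerate or inconsistent geometry (collinear markers, parallel axes, ...)."""


class SignalError(TorsionGaitError):
    """A time series is too short, empty, or otherwise unusable."""


class EventError(SignalError):
    """Gait events could not be detected (e.g. no force-threshold crossing)."""


class RecruitmentError(TorsionGaitError):
    """Muscle recruitment infeasible: net moments exceed muscle capacity.

    Carries the name of the violated generalized coordinate when known.
    """

    def __init__(self, message: str, dof: str | None = None):
        super().__init__(message)
        self.dof = dof


class ConfigError(TorsionGaitError):
    """Invalid run configuration."""
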