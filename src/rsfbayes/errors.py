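"""Exception hierarchy for rsfbayes.

All package-specific failures derive from :class:`RsfError` so callers can
catch one base class at the CLI boundary.
"""


class RsfError(Exception):
    """Base class for all rsfbayes errors."""


class DegenerateGeometryError(RsfError):
    """Fewer than three points, or all points collinear: no home range."""


class InfeasibleDesignError(RsfError):
    """Availability sampling cannot place the requested points.

    Raised when the feasible fraction of the home range (inside the polygon
    and outside every exclusion circle) is estimated to be below the
    configured floor after the attempt budget is spent.
    """

    def __init__(self, message: str, feasible_fraction: float):
        super().__init__(message)
        self.feasible_fraction = feasible_fraction


class OutOfBoundsError(RsfError):
    """A sampling circle extends beyond the landscape extent."""


class TrackOrderError(RsfError):
    """Telemetry fixes are not sorted by time."""


class DegenerateIndividualError(RsfError):
    """An individual contributes only used or only available records."""


class FormulaMismatchError(RsfError):
    """A requested covariate or term is not part of the fitted formula."""


class ConfigError(RsfError):
    """Invalid sampler or run configuration."""


class SimulationInfeasibleError(RsfError):
    """Selection-weighted rejection sampling acceptance rate collapsed."""


class NumericError(RsfError):
    """Non-finite quantity encountered during likelihood evaluation."""
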