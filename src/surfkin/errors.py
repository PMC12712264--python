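"""Exception hierarchy for surfkin.

Validation errors map to CLI exit code 2, numerical failures to exit code 3.
"""


class SurfkinError(Exception):
    """Base class for all package errors."""


class ValidationError(SurfkinError, ValueError):
    """Invalid user input: bad configuration values, malformed files, domain errors."""


class ConfigurationError(ValidationError):
    """Inconsistent parameter configuration (e.g. threshold ordering, zero yields)."""


class SimulationError(SurfkinError, RuntimeError):
    """Numerical failure during ODE integration."""


class FeedStartError(SimulationError):
    """The glucose threshold triggering the feed was never crossed."""


class ObjectiveError(SurfkinError, ValueError):
    """Objective undefined (e.g. no overlapping observation points for RMSE)."""


class FitError(SurfkinError, RuntimeError):
    """Parameter estimation failed (all restarts crashed the simulator)."""
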