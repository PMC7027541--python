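"""Exception hierarchy for vplatelet."""


class VPlateletError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VPlateletError):
    """A model or pipeline configuration is incomplete or inconsistent."""


class SimulationError(VPlateletError):
    """The ODE integrator failed or produced an invalid state.

    Carries the solver diagnostic message where available.
    """


class CalibrationError(VPlateletError):
    """Rate calibration could not satisfy its target; reports best residual."""


class SaturationError(VPlateletError):
    """A bead standard curve failed the R-squared acceptance gate."""
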