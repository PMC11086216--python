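"""Exception hierarchy for emg2torque."""


class Emg2TorqueError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(Emg2TorqueError, ValueError):
    """A scalar parameter is outside its admissible range."""


class InvalidInputError(Emg2TorqueError, ValueError):
    """An input signal violates a precondition (sign, range, length)."""


class ConfigurationError(Emg2TorqueError, ValueError):
    """A model configuration is inconsistent or unstable."""


class GeometryError(Emg2TorqueError, RuntimeError):
    """Musculotendon geometry became infeasible (e.g. negative tendon length)."""


class IntegrationError(Emg2TorqueError, RuntimeError):
    """Fiber-length integration left its admissible range."""

    def __init__(self, message, muscle=None, step=None):
        super().__init__(message)
        self.muscle = muscle
        self.step = step


class TrialFormatError(Emg2TorqueError, ValueError):
    """A trial file is malformed or internally inconsistent."""
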