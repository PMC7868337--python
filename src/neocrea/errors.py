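"""Exception types raised by the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class ConfigError(ValidationError):
    """A configuration file is missing required keys or holds bad values."""


class CalibrationError(RuntimeError):
    """The calibration could not produce a usable parameter set."""
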