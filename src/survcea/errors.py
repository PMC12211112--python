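"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input (parameter file, schedule, anchor set, ...) failed validation."""


class CalibrationError(RuntimeError):
    """A calibration target could not be reached within the search interval."""
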