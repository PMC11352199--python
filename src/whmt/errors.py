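"""Exception hierarchy for diagram scoring and simulation."""


class WHMTError(Exception):
    """Base class for all package errors."""


class CalibrationError(WHMTError):
    """A calibration is invalid or does not match the diagram it is applied to."""


class InputError(WHMTError):
    """Malformed input data (non-finite coordinates, negative distances, ...)."""


class DegenerateInputError(WHMTError):
    """Too few placements for the requested metric to be defined."""


class ValidationError(WHMTError):
    """A record or file violates the data-model invariants.

    ``problems`` carries one human-readable message per violation, with row
    numbers when the source was a file.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class ConfigError(WHMTError):
    """An invalid generator or run configuration (e.g. probabilities not summing to 1)."""
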