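"""Exception hierarchy shared across the pipeline."""


class PullkinError(Exception):
    """Base class for all package errors."""


class FormatError(PullkinError):
    """A trajectory table does not match any supported dialect."""


class StructuralError(PullkinError):
    """A table parsed but its contents are internally inconsistent."""


class InputError(PullkinError):
    """An input signal or value violates an operation's precondition."""


class ParameterError(PullkinError):
    """A configuration value is out of range (e.g. cutoff above Nyquist)."""


class ConfigurationError(PullkinError):
    """A requested channel, preset, or option does not exist."""


class DegenerateInputError(InputError):
    """Input is valid but degenerate (zero variance, no epochs, ...)."""
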