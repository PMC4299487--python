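"""Exception hierarchy; the CLI maps each class to a distinct exit code."""


class EpleioError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class InputError(EpleioError):
    """A precondition on user input is violated (bad ratio, too few taxa...)."""

    exit_code = 2


class ParseError(EpleioError):
    """A file could not be parsed in the stated format."""

    exit_code = 3


class SaturationError(EpleioError):
    """Sequence divergence is saturated; distances are undefined."""

    exit_code = 4


class EstimationError(EpleioError):
    """The estimator is undefined for these data (no variation, g >= 1...)."""

    exit_code = 5
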