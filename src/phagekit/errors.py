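"""Exception hierarchy shared across phagekit."""


class PhageKitError(Exception):
    """Base class for all phagekit errors."""


class InvalidInputError(PhageKitError, ValueError):
    """An input value violates a documented precondition."""


class InsufficientDataError(PhageKitError):
    """Too few data points to run the requested estimator."""


class NoAdsorptionError(PhageKitError):
    """No measurable adsorption; burst size is undefined."""


class ParseError(PhageKitError):
    """A file could not be parsed; message carries location information."""
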