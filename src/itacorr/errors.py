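"""Exception hierarchy shared across the package."""


class ItacorrError(Exception):
    """Base class for all package errors."""


class ParseError(ItacorrError):
    """A structured text file (XYZ, Molden, CSV table) could not be parsed."""


class ConfigurationError(ItacorrError):
    """Invalid configuration: unknown element, unsupported grid order, bad task."""


class ContractError(ItacorrError):
    """Caller violated an interface contract (misaligned arrays, wrong sizes)."""


class CapabilityError(ItacorrError):
    """Operation requires a capability the object lacks (e.g. orbital densities)."""


class UnsupportedFormatError(ParseError):
    """File is syntactically valid but uses an unsupported variant."""


class DomainError(ItacorrError, ValueError):
    """Mathematical domain violation (bad Renyi order, log of non-positive)."""


class DegenerateFitError(ItacorrError):
    """Regression input is degenerate (constant descriptor column)."""


class InsufficientDataError(ItacorrError):
    """Too few points to fit."""
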