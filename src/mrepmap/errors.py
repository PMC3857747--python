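"""Exception hierarchy shared by all pipeline stages."""


class MrepMapError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MrepMapError):
    """A file could not be parsed as the expected format."""


class ValidationError(MrepMapError):
    """An input object violates a structural invariant (bad spacing,
    open polygon, mismatched topology, empty input ...)."""


class DomainError(MrepMapError):
    """A coordinate or point lies outside the domain of the requested
    mapping (e.g. outside the model + rind)."""


class OverlapError(MrepMapError):
    """Image overlap after a candidate transform is below the minimum
    fraction required for a meaningful similarity value."""


class RegistrationError(MrepMapError):
    """No registration start satisfied its preconditions."""


class QualityError(MrepMapError):
    """A computed quantity is too degraded to be trusted (e.g. most
    intensity profiles truncated at the image border)."""
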