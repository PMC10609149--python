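"""Exception hierarchy shared across the package."""


class MetabotreeError(Exception):
    """Base class for all package errors."""


class ValidationError(MetabotreeError):
    """A value or combination of values violates a documented invariant."""


class FormatError(MetabotreeError):
    """An input file or record does not match the expected format."""


class CapabilityError(MetabotreeError):
    """A requested backend or optional dependency is unavailable."""
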