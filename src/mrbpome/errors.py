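"""Exception hierarchy shared across the package."""


class MrbpomeError(Exception):
    """Base class for all package errors."""


class FormatError(MrbpomeError):
    """A file does not conform to its documented format."""


class ValidationError(MrbpomeError):
    """Input values violate a documented invariant."""


class ConfigurationError(MrbpomeError):
    """The sample design or configuration is unusable for the requested step."""
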