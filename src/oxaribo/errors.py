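"""Exception hierarchy shared across the package."""


class OxariboError(Exception):
    """Base class for all package errors."""


class FormatError(OxariboError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(OxariboError):
    """Input data violates a domain invariant."""


class ConfigurationError(OxariboError):
    """Parameters or reference tables are inconsistent or incomplete."""


class FitError(OxariboError):
    """A model fit could not be carried out on the given data."""
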