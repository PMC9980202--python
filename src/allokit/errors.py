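"""Exception hierarchy shared across the package."""


class AllokitError(Exception):
    """Base class for all package errors."""


class ParseError(AllokitError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(AllokitError):
    """Input data violates a documented contract."""


class ConfigurationError(AllokitError):
    """A run configuration or selection is inconsistent or matches nothing."""


class SyntheticSpecError(AllokitError):
    """A synthetic-ensemble specification violates its invariants."""
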