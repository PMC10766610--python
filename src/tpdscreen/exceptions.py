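"""Exception hierarchy shared by all stages."""


class TpdScreenError(Exception):
    """Base class for all package errors."""


class FormatError(TpdScreenError):
    """A file does not have the expected structure (missing column, empty file)."""


class ValidationError(TpdScreenError):
    """Well-formed input carries values that violate the data model."""


class ConfigError(TpdScreenError):
    """A simulation or pipeline configuration is inconsistent."""


class FitError(TpdScreenError):
    """A curve fit could not be performed or did not converge."""
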