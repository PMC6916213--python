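"""Exception hierarchy shared across the package."""


class CopdAtlasError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CopdAtlasError, ValueError):
    """A configuration object violates its invariants."""


class ValidationError(CopdAtlasError, ValueError):
    """A data record violates a domain invariant."""


class CorpusParseError(CopdAtlasError, ValueError):
    """A corpus file could not be parsed; message names the offending line."""
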