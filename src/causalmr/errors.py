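"""Exception hierarchy shared across the package."""


class CausalMRError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CausalMRError):
    """A user-supplied configuration (column map, flag, config file) is invalid."""


class ValidationError(CausalMRError):
    """Input data violate a contract (duplicate ids, bad SEs, rank deficiency...)."""
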