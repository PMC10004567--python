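"""Exception hierarchy for the claimsprev pipeline."""


class ClaimsPrevError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ClaimsPrevError, ValueError):
    """A required column is missing or a table does not match its schema."""


class MalformedCodeError(ClaimsPrevError, ValueError):
    """An ICD-10 code is empty or otherwise unusable."""


class ConfigurationError(ClaimsPrevError, ValueError):
    """A requested year, grid, or option is inconsistent with the inputs."""


class ConsistencyError(ClaimsPrevError, ValueError):
    """Two tables that must describe the same universe disagree."""


class EmptyStratumError(ClaimsPrevError, ValueError):
    """A prevalence denominator is zero for the requested stratum."""


class DoubleCountError(ClaimsPrevError, ValueError):
    """The same person appears in case sets that must be disjoint."""


class PairingError(ClaimsPrevError, ValueError):
    """A benchmark value does not match the stratum of the estimate."""


class SelectionError(ClaimsPrevError, ValueError):
    """Algorithm selection was requested for an empty family."""


class ParameterError(ClaimsPrevError, ValueError):
    """A numeric parameter is outside its allowed range."""
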