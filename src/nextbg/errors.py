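"""Exception hierarchy shared across the package."""


class NextBGError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NextBGError, ValueError):
    """A configuration value violates its invariant; names the offending field."""


class ValidationError(NextBGError, ValueError):
    """Input data violates a structural invariant (ordering, ranges)."""


class ParseError(NextBGError, ValueError):
    """A delimited-text input could not be parsed; carries a row reference."""


class InclusionError(NextBGError, ValueError):
    """An admission fails the minimum-reading inclusion criterion."""


class ContractError(NextBGError, ValueError):
    """A function precondition was violated by the caller."""


class SchemaError(NextBGError, ValueError):
    """A required column is missing from a tabular input."""


class UndefinedMetricError(NextBGError, ValueError):
    """A correlation/metric is undefined for the given input (zero variance)."""


class PipelineStageError(NextBGError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
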