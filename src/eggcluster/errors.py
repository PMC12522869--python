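"""Exception hierarchy for the eggcluster pipeline."""


class EggClusterError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EggClusterError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(EggClusterError, ValueError):
    """An input table fails validation (missing column, bad value, inconsistent sums)."""


class DegenerateTestError(EggClusterError):
    """A statistical test cannot be computed (e.g. all paired differences are zero)."""


class InsufficientDataError(EggClusterError):
    """Too few observations to compute the requested quantity."""


class UndefinedMetricError(EggClusterError):
    """The metric's denominator is empty (e.g. no focal eggs in clusters)."""
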