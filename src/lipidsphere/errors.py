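"""Exception hierarchy for lipidsphere.

Every error raised by the library derives from :class:`LipidSphereError` so
callers (and the CLI) can distinguish domain failures from programming bugs.
"""


class LipidSphereError(Exception):
    """Base class for all lipidsphere errors."""


class DomainError(LipidSphereError):
    """An input violates a mathematical or physiological precondition."""


class SchemaError(LipidSphereError):
    """A required column, field or model feature is missing or malformed."""


class UnitError(LipidSphereError):
    """Units of the supplied values do not match what the consumer expects."""


class DegenerateDistributionError(LipidSphereError):
    """A feature is constant where a spread is required (quantiles, z-scores)."""


class FitError(LipidSphereError):
    """Model fitting cannot proceed (single-class outcome, too few rows)."""


class ConvergenceError(FitError):
    """Maximum-likelihood fit failed to converge (e.g. complete separation)."""


class ConfigError(LipidSphereError):
    """A configuration object is internally inconsistent."""
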