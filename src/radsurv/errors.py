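"""Exception hierarchy.

All radsurv exceptions derive from :class:`RadsurvError` and from
:class:`ValueError`, so callers can catch either the package-specific or the
generic type.
"""


class RadsurvError(ValueError):
    """Base class for all radsurv errors."""


class DomainError(RadsurvError):
    """An argument lies outside the mathematical domain of an operation
    (negative dose, non-positive age, log of a non-positive quantity, ...)."""


class ConfigurationError(RadsurvError):
    """A model specification, weight set or settings object is invalid."""


class DataError(RadsurvError):
    """Input data are missing or inconsistent (baseline coverage gaps,
    missing method estimates, malformed tables)."""
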