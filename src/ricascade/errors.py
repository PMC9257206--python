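"""Typed exceptions shared across the package.

Undefined indices raise rather than return sentinels, so that report
generation can mark individual barriers as "not estimable" instead of
silently propagating NaN through the cascade.
"""


class RICascadeError(Exception):
    """Base class for all package errors."""


class UndefinedIndexError(RICascadeError):
    """An RI index is undefined because its denominator is zero
    (no conspecific and no heterospecific success observed)."""


class UndefinedConstancyError(RICascadeError):
    """The constancy index denominator vanishes with c != 1."""


class EmptyInputError(RICascadeError):
    """An operation received no usable records."""


class NotEstimable(RICascadeError):
    """A barrier or bout cannot be estimated from the available data;
    callers aggregate around it instead of failing the whole analysis."""


class ConfigError(RICascadeError):
    """A simulation or run configuration is invalid."""


class SchemaError(RICascadeError):
    """A CSV input violates the expected schema."""
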