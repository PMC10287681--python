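"""Exception hierarchy shared across the pipeline."""


class SoilnetError(Exception):
    """Base class for all package errors."""


class ConfigError(SoilnetError):
    """A configuration field is missing, mistyped or out of range."""


class DataError(SoilnetError):
    """Input data violate a precondition (empty, zero totals, missing year...)."""


class DegenerateSeriesError(DataError):
    """A series is constant where variation is required (sd = 0)."""


class EmptyResultError(DataError):
    """A filtering or subsampling step removed everything."""


class SpecificationError(SoilnetError):
    """A model specification is invalid (e.g. cyclic path diagram)."""
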