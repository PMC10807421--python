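"""Structured errors raised by the pipeline.

Every error names the file, column or stratum it concerns so that a failed
run can be diagnosed from the message alone.
"""


class OtosignalError(Exception):
    """Base class for all structured pipeline errors."""


class VaersLoadError(OtosignalError):
    """A report, denominator or mapping file could not be parsed."""


class MissingColumnError(VaersLoadError):
    def __init__(self, path: str, column: str):
        self.path = str(path)
        self.column = column
        super().__init__(f"file {path!r} is missing required column {column!r}")


class MappingConfigError(OtosignalError):
    """The preferred-term group mapping violates its invariants."""


class UnmappedTermError(MappingConfigError):
    def __init__(self, term: str):
        self.term = term
        super().__init__(f"preferred term {term!r} is not mapped to any group")


class MissingDenominatorError(OtosignalError):
    def __init__(self, series: str, axis: str, level: str):
        self.key = (series, axis, level)
        super().__init__(
            f"no vaccinated-population denominator for series={series} "
            f"axis={axis} level={level}"
        )


class UndefinedShareError(OtosignalError):
    """Percentage share requested against a zero total."""


class DegenerateTableError(OtosignalError):
    """A contingency table has a zero row or column margin."""


class UnsupportedShapeError(OtosignalError):
    """The requested test does not support the table's shape."""


class BackgroundZeroError(OtosignalError):
    """PRR background cell M - m is zero and no continuity correction is enabled."""


class ConfigurationError(OtosignalError):
    """A run or simulation configuration is invalid."""
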