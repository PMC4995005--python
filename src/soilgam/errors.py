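"""Exception hierarchy.

Errors are split by origin so the CLI can map them onto exit codes:
configuration problems (exit 2), data problems (exit 3) and numerical
failures (exit 4).
"""


class SoilGamError(Exception):
    """Base class for all package errors."""


class ConfigError(SoilGamError):
    """Invalid or inconsistent run configuration."""


class DataError(SoilGamError):
    """Invalid input data."""


class SchemaError(DataError):
    """A required column is missing or unmappable."""

    def __init__(self, missing, table=""):
        self.missing = list(missing)
        self.table = table
        super().__init__(
            f"missing column(s) {self.missing!r}" + (f" in table {table!r}" if table else "")
        )


class IntegrityError(DataError):
    """Duplicate design cells or violated design structure."""


class ReferentialError(DataError):
    """A respiration or endmember row references an unknown site."""


class NumericError(SoilGamError):
    """Numerical failure during model fitting or partitioning."""


class DegenerateMixingError(NumericError):
    """Isotope endmembers too close to separate the two carbon sources."""


class UndefinedPEError(NumericError):
    """Priming-effect ratio undefined (control soil-derived flux <= 0)."""


class BasisError(NumericError):
    """Spline basis cannot be built (too few distinct covariate values)."""


class SingularFitError(NumericError):
    """Model matrix is rank deficient beyond repair."""


class DegenerateResponseError(NumericError):
    """Response has no variance (null deviance zero)."""
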