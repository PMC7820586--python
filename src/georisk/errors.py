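"""Exception hierarchy. Each class maps to a distinct CLI exit code."""


class GeoRiskError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(GeoRiskError):
    """Invalid parameter value (non-positive range, k < 2, bad fraction...)."""

    exit_code = 2


class SamplingError(GeoRiskError):
    """Requested sample cannot be drawn (too few eligible cells...)."""

    exit_code = 3


class EstimationError(GeoRiskError):
    """Empirical estimate undefined (empty lag bins, constant counts...)."""

    exit_code = 4


class FittingError(GeoRiskError):
    """Model fit failed to converge or is degenerate."""

    exit_code = 5


class AlignmentError(GeoRiskError):
    """Raster layers or point sets do not share one grid."""

    exit_code = 6


class SchemaError(GeoRiskError):
    """Malformed input file (missing columns, non-numeric coordinates...)."""

    exit_code = 7


class UndefinedStatisticError(EstimationError):
    """Statistic has zero variance or an all-zero/constant input."""

    exit_code = 8
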