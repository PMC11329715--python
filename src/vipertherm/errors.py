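"""Exception hierarchy shared across the pipeline stages."""


class ViperthermError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ViperthermError):
    """A generator or run configuration violates its invariants."""


class InsufficientDataError(ViperthermError):
    """Too few observations to run the requested estimator."""


class DegenerateInputError(ViperthermError):
    """Input has no variance (or is otherwise degenerate) where variance is required."""


class InvalidBoundsError(ViperthermError):
    """A set-point interval with lower > upper."""


class UndefinedIndexError(ViperthermError):
    """An index whose denominator vanishes (e.g. E with d_e = 0, E_x with no overlap)."""


class MalformedSeriesError(ViperthermError):
    """A time series of the wrong length or with broken cadence."""


class MissingScenarioError(ViperthermError):
    """A climate scenario requested but absent from the cell's data."""


class InvalidTreeError(ViperthermError):
    """A phylogeny unusable for the requested operation (e.g. single tip)."""


class DegenerateTraitError(ViperthermError):
    """A constant trait vector, for which signal statistics are undefined."""


class MatchingError(ViperthermError):
    """A spot record that cannot be paired with any operative-temperature reading."""


class MissingInputError(ViperthermError):
    """A pipeline stage invoked without a required input table."""
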