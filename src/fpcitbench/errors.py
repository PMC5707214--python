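"""Exception types shared across the package."""


class FpcitBenchError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FpcitBenchError, ValueError):
    """A generator, method or grid parameter violates its invariants."""


class InvalidGeometryError(FpcitBenchError, ValueError):
    """Phantom masks overlap illegally or cannot be mirrored."""


class DegenerateReferenceError(FpcitBenchError, ValueError):
    """Occipital reference region has non-positive mean uptake."""


class InsufficientComparatorsError(FpcitBenchError, ValueError):
    """Too few comparison subjects to estimate a normal limit."""


class DegenerateRegressionError(FpcitBenchError, ValueError):
    """Age regression is undefined (all comparator ages identical)."""


class InsufficientDataError(FpcitBenchError, ValueError):
    """Not enough rows to fit a transformer or classifier."""


class MissingInputError(FpcitBenchError, KeyError):
    """A required per-subject input (e.g. a volume) is absent."""


class StratificationError(FpcitBenchError, ValueError):
    """A class is too small to stratify into the requested folds."""


class ConfigurationError(FpcitBenchError, ValueError):
    """A method specification is incomplete or inconsistent."""


class UndefinedMetricError(FpcitBenchError, ValueError):
    """A confusion metric is undefined for the given labels."""
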