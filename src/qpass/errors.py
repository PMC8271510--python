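"""Exception hierarchy for the qpass package."""


class QPassError(Exception):
    """Base class for all qpass errors."""


class InputError(QPassError, ValueError):
    """A value violates an operation's preconditions."""


class AlignmentError(QPassError, ValueError):
    """Two sensor streams are not aligned in time or length."""


class ConfigurationError(QPassError, ValueError):
    """A run configuration value is invalid (weights, filter, paths)."""


class AnnotationError(QPassError, ValueError):
    """A pass-event annotation is inconsistent with the recording."""


class GeometryError(QPassError, ValueError):
    """Ball-impact geometry is degenerate (non-positive radius or side)."""


class ReferenceGroupError(QPassError, ValueError):
    """The reference cohort is missing data needed to build references."""


class AggregationError(QPassError, ValueError):
    """A player x pass-type group is too small to aggregate."""


class IncompleteDesignError(QPassError, ValueError):
    """A repeated-measures table has missing cells."""


class UndefinedStatisticError(QPassError, ValueError):
    """A statistic is undefined for the given inputs (zero mean/SD)."""


class ReconciliationError(QPassError, ValueError):
    """Annotations and recordings do not match up."""
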