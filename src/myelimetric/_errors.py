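"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`MyeliMetricError` so that callers
(and the CLI) can attach the stage name without string matching.
"""


class MyeliMetricError(Exception):
    """Base class for all package errors."""


class MissingCounterpartError(MyeliMetricError):
    """A ``<prefix>_Ax`` column exists without its ``<prefix>_My`` twin (or
    vice versa)."""


class EmptyWorkbookError(MyeliMetricError):
    """The workbook holds no paired measurement columns or no data rows."""


class DegenerateControlError(MyeliMetricError):
    """The control dataset cannot support a six-bin scheme (too few records,
    all values identical, or collapsing quantile edges)."""


class EmptyCellError(MyeliMetricError):
    """A group x bin cell holds no observations, so the factorial ANOVA is
    not estimable."""


class SimulationInfeasibleError(MyeliMetricError):
    """Rejection sampling against the fiber cap exhausted its redraw budget."""


class InvariantViolationError(MyeliMetricError):
    """An internal contract was broken (e.g. non-positive input reached the
    g-ratio computation)."""
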