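"""Exception hierarchy for the stormcohort pipeline."""


class StormCohortError(Exception):
    """Base class for all stormcohort errors."""


class ValidationError(StormCohortError):
    """Invalid input data or configuration."""


class MissingDataError(StormCohortError):
    """Required observations are absent (e.g. no station reports for a date)."""


class DegenerateGroupError(StormCohortError):
    """A comparison group is empty or a statistic is undefined on the input."""


class ConvergenceError(StormCohortError):
    """An iterative fit failed to converge within its iteration cap."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
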