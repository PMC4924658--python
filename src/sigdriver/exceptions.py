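"""Exception hierarchy used across the pipeline stages."""


class SigdriverError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SigdriverError, ValueError):
    """Invalid simulation or run configuration."""


class MergeError(SigdriverError):
    """Cohorts cannot be merged (empty gene intersection, duplicate samples)."""


class PlanningError(SigdriverError):
    """A virtual-dataset plan is infeasible for the cohort at hand."""


class ConvergenceError(SigdriverError):
    """Iterative shrinkage failed to converge; carries the last iterate.

    Attributes
    ----------
    last_result : object
        The state reached at the final iteration, for inspection.
    """

    def __init__(self, message, last_result=None):
        super().__init__(message)
        self.last_result = last_result


class ParseError(SigdriverError):
    """A malformed input line; carries file and line number."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


class NetworkError(SigdriverError):
    """Network construction or reduction failed (empty graph, bad terminals)."""


class AnalysisError(SigdriverError):
    """A statistical routine received degenerate input (constant vector, no events)."""


class PipelineStageError(SigdriverError):
    """A pipeline stage aborted; carries the stage name and the original error."""

    def __init__(self, stage, original):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
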