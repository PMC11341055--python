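"""Exception hierarchy for the alugs pipeline."""


class AlugsError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(AlugsError, ValueError):
    """An infeasible or inconsistent configuration was supplied."""


class LayoutError(AlugsError, ValueError):
    """Field layout capacity cannot accommodate the requested entries."""


class QCError(AlugsError, ValueError):
    """Quality-control failure (e.g. no markers pass the filters)."""


class ConvergenceError(AlugsError, RuntimeError):
    """Iterative model fit failed to converge.

    Carries the optimizer trace in ``trace`` (list of objective values).
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class DegenerateDataError(AlugsError, ValueError):
    """Input data is degenerate for the requested statistic (zero variance, etc.)."""


class LeakageError(AlugsError, RuntimeError):
    """A cross-validation audit found validation records in the training set."""
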