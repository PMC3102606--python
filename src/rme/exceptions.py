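"""Exception hierarchy for the rme package."""


class RmeError(Exception):
    """Base class for all rme-specific errors."""


class MatrixFormatError(RmeError, ValueError):
    """A mutation-matrix file (or in-memory construction) is malformed."""


class CallValidationError(RmeError, ValueError):
    """An aberration call references a sample or gene outside the declared universe."""


class UndefinedStatisticError(RmeError, ValueError):
    """A statistic is undefined for the given input (e.g. exclusivity with no covered sample)."""


class DegenerateBackgroundError(RmeError, ValueError):
    """The background aberration frequency is degenerate (all-zero or all-one matrix)."""


class ModuleTooSmallError(RmeError, ValueError):
    """A candidate module has fewer than two genes."""


class SimulationConfigError(RmeError, ValueError):
    """Simulation parameters are infeasible or inconsistent."""
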