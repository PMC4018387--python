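"""Exception types shared across the package."""


class MLPDError(Exception):
    """Base class for package errors."""


class BlockConsistencyError(MLPDError):
    """A subject has some, but not all, entries of a source block missing."""


class NoTrainableTaskError(MLPDError):
    """No availability pattern has enough subjects in both classes."""


class ScreeningEmptyError(MLPDError):
    """Feature screening removed every feature of some task."""


class LPInfeasibleError(MLPDError):
    """The discriminant LP has no feasible point for the given parameters."""


class SolverError(MLPDError):
    """The LP solver terminated abnormally."""


class PatternMismatchError(MLPDError):
    """A subject's availability pattern matches no fitted task."""
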