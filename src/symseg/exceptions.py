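"""Exception hierarchy for symseg.

Exit-code mapping used by the CLI: usage errors -> 2 (click), input /
degenerate-data errors -> 3, numeric failures during evolution -> 4.
"""


class SymsegError(Exception):
    """Base class for all symseg errors."""


class ParameterError(SymsegError, ValueError):
    """A parameter violates its contract (non-positive sigma, bad shape, ...)."""


class InputError(SymsegError, ValueError):
    """An input file or array is unusable (shape mismatch, unreadable, ...)."""


class DegenerateInputError(InputError):
    """Input is formally valid but degenerate (all-zero edge map, empty mask)."""


class TipNotFoundError(SymsegError, RuntimeError):
    """No corner candidate survived thresholding in the tip search band."""


class NumericFailureError(SymsegError, ArithmeticError):
    """The level-set evolution produced non-finite values."""

    def __init__(self, iteration: int, message: str | None = None):
        self.iteration = iteration
        super().__init__(message or f"non-finite level-set values at iteration {iteration}")
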