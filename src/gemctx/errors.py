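"""Exception hierarchy shared across the package."""


class GemctxError(Exception):
    """Base class for all package errors."""


class ValidationError(GemctxError):
    """A model or table violates a structural invariant."""


class GPRParseError(GemctxError):
    """A gene-protein-reaction rule string could not be parsed.

    Carries the character position of the offending token when known.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class FormulaError(GemctxError):
    """A chemical formula string could not be parsed."""


class UnknownCompositionError(GemctxError):
    """A metabolite participating in a balance check has no formula."""


class SolverError(GemctxError):
    """An LP/MILP did not return a usable solution."""

    def __init__(self, message: str, status: str = "error"):
        self.status = status
        super().__init__(message)


class InfeasibleError(SolverError):
    def __init__(self, message: str = "problem is infeasible"):
        super().__init__(message, status="infeasible")


class ScenarioError(GemctxError):
    """A simulation scenario references a species the model lacks."""
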