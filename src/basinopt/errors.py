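"""Exception hierarchy for basinopt."""


class BasinoptError(Exception):
    """Base class for all basinopt errors."""


class ValidationError(BasinoptError):
    """Input data violates a schema or cross-reference invariant.

    Carries a list of human-readable problem descriptions in ``problems``.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class CycleError(ValidationError):
    """The river network's downstream links contain a cycle."""


class InfeasibleFlowError(BasinoptError):
    """Mass balance cannot be satisfied: withdrawals plus losses exceed inflow."""

    def __init__(self, reach_id, deficit):
        self.reach_id = reach_id
        self.deficit = float(deficit)
        super().__init__(
            f"negative outflow at reach {reach_id!r}: deficit {self.deficit:.6g}"
        )


class InvalidParameterError(BasinoptError):
    """A model parameter is outside its admissible domain (e.g. beta >= 0)."""


class ConstraintViolationError(BasinoptError):
    """An explicit model constraint is violated (e.g. urban demand > supply)."""


class SolverError(BasinoptError):
    """The optimizer failed to converge or reported infeasibility."""

    def __init__(self, message, diagnostics=None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class UnboundedError(SolverError):
    """The optimization problem has no finite optimum."""
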