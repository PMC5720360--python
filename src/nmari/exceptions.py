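"""Exception hierarchy.

Validation and identifiability problems (exit code 2 in the CLI) are kept
distinct from numerical/convergence failures (exit code 3) so callers can
react appropriately.
"""


class NmaError(Exception):
    """Base class for all package errors."""


class InvalidDataError(NmaError, ValueError):
    """Input data violate a documented invariant (schema, counts, ranges)."""


class DegenerateStudyError(InvalidDataError):
    """A study cannot contribute a finite contrast (e.g. empty cells)."""


class IdentifiabilityError(NmaError):
    """The requested model is not identifiable from the supplied network."""


class DisconnectedNetworkError(IdentifiabilityError):
    """The treatment graph is not connected; basic parameters are not estimable."""

    def __init__(self, components):
        self.components = [sorted(c) for c in components]
        super().__init__(
            "treatment network is disconnected; components: "
            + "; ".join("{" + ", ".join(c) + "}" for c in self.components)
        )


class NumericalError(NmaError):
    """A matrix factorization or root solve failed."""


class ConvergenceError(NmaError):
    """An iterative optimizer failed to converge from every start."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
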