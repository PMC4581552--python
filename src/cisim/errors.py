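"""Exception hierarchy for cisim."""

__all__ = [
    "CisimError",
    "InvalidInputError",
    "InvalidConfigError",
    "FitFailureError",
    "InvalidMeshError",
    "DegeneratePlaneError",
    "InsufficientCoverageError",
    "InvalidPlanError",
    "InfeasiblePlanError",
]


class CisimError(Exception):
    """Base class for all cisim errors."""


class InvalidInputError(CisimError, ValueError):
    """Input data violates a precondition."""


class InvalidConfigError(CisimError, ValueError):
    """Configuration values are inconsistent or out of range."""


class FitFailureError(CisimError):
    """A model fit did not converge; carries the best residual reached."""

    def __init__(self, message: str, best_rms: float | None = None):
        super().__init__(message)
        self.best_rms = best_rms


class InvalidMeshError(CisimError):
    """Surface mesh unusable for cross-section sampling."""


class DegeneratePlaneError(CisimError):
    """Point set is rank-deficient; no unique regression plane exists."""


class InsufficientCoverageError(CisimError):
    """Contour does not cover enough of the basal turn for the measurement."""


class InvalidPlanError(CisimError, ValueError):
    """Insertion plan is inconsistent with the profile or contour."""


class InfeasiblePlanError(CisimError):
    """No plan satisfies the optimization constraints; names the violated cap."""
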