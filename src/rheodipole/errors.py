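"""Exception hierarchy shared across the package."""


class RheodipoleError(Exception):
    """Base class for all package-specific errors."""


class SingularityError(RheodipoleError, ValueError):
    """Evaluation point coincides (within guard radius) with a vortex singularity."""


class DomainError(RheodipoleError, ValueError):
    """Input lies outside the physical/mathematical domain of an operation."""


class ConvergenceError(RheodipoleError, RuntimeError):
    """An iterative computation failed to meet its tolerance within its budget."""

    def __init__(self, message: str, last_increment: float | None = None):
        super().__init__(message)
        self.last_increment = last_increment


class ContractError(RheodipoleError, ValueError):
    """A caller violated a documented precondition (e.g. non-equilibrium input)."""
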