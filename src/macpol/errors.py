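"""Exception hierarchy shared across the package."""


class MacpolError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MacpolError):
    """A model object references something that does not exist or is ill-formed."""


class DomainError(MacpolError, ValueError):
    """A numeric argument is outside its allowed domain (e.g. negative amount)."""


class ValidationError(MacpolError):
    """A network failed validation; carries the violation report."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "network validation failed:\n  " + "\n  ".join(self.violations)
        )


class NonConvergenceError(MacpolError):
    """Pre-equilibration did not reach a resting state within the horizon."""


class SolverError(MacpolError):
    """The ODE integrator failed mid-run."""


class UnsupportedFeatureError(MacpolError):
    """An input file uses constructs outside the supported subset."""
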