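"""Exception hierarchy for the nursevam pipeline."""


class NurseVamError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NurseVamError):
    """Invalid simulation or pipeline configuration."""


class SimulationError(NurseVamError):
    """The simulated scenario is infeasible (e.g. staffing cannot cover beds)."""


class IntegrityError(NurseVamError):
    """Referential-integrity violation in a raw extract (e.g. event for unknown patient)."""


class AssemblyError(NurseVamError):
    """Cohort assembly produced an unusable dataset (e.g. empty after exclusions)."""


class FitError(NurseVamError):
    """Model estimation failed; carries diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class SeparationError(FitError):
    """Perfect separation made the unpenalized MLE diverge; a ridge penalty fixes it."""


class ValidationError(NurseVamError):
    """Cross-sample validation is not computable (e.g. no overlapping nurses)."""


class InsufficientDataError(NurseVamError):
    """Too few observations for the requested statistic."""


class SchemaError(NurseVamError):
    """Input files do not conform to the canonical table schema."""


class PowerError(NurseVamError):
    """Power analysis is undefined for the given proportions."""
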