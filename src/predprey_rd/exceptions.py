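"""Exception hierarchy shared across the package."""


class PredPreyError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PredPreyError, ValueError):
    """A model or algorithm parameter violates its sign/range constraints."""


class DomainError(PredPreyError, ValueError):
    """An input lies outside the mathematical domain of the operation."""


class HypothesisError(PredPreyError, ValueError):
    """A functional response violates a structural hypothesis required up front."""


class SimulationError(PredPreyError, RuntimeError):
    """Time integration failed or produced inadmissible values."""


class DiagnosticsError(PredPreyError, RuntimeError):
    """A trajectory diagnostic cannot be computed (e.g. trajectory too short)."""
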