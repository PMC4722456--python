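"""Exception and warning types shared across the package."""


class KineticsError(Exception):
    """Base class for all package-specific errors."""


class IncompletePresetError(KineticsError):
    """A required kinetic parameter is missing from the genotype preset."""


class InvalidConditionError(KineticsError, ValueError):
    """A ligand concentration or other experimental condition is invalid."""


class ConstructionError(KineticsError):
    """Elementary rate constants cannot be built under the given constraints."""


class SignalSchemeMismatchError(KineticsError):
    """Requested optical signal is not defined for the simulated scheme."""


class UndersampledError(KineticsError):
    """Trace duration too short to resolve the relaxation (< 3 half-lives)."""


class FitFailureError(KineticsError):
    """Nonlinear least squares did not converge after restarts."""


class UnreliableRateError(FitFailureError):
    """Fitted rate too fast for the sampling interval to resolve."""


class UnsaturatedTitrationError(KineticsError):
    """Titration indistinguishable from a straight line; plateau undefined."""


class DoubleSubtractionError(KineticsError):
    """Basal ATPase rates were already subtracted from this dataset."""


class PoorConditioningWarning(UserWarning):
    """Ligand grid poorly conditioned for the requested fit."""


class CurvatureWarning(UserWarning):
    """Linear-regime fit shows significant lack of fit (visible curvature)."""


class UnreliableRateWarning(UserWarning):
    """Generated or fitted rate exceeds the resolvability cap."""


class WideIntervalWarning(UserWarning):
    """Plateau unsampled; saturation parameters weakly constrained."""
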