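"""Exception hierarchy shared across the package."""


class SecmalError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SecmalError):
    """A plain-text input file does not conform to the expected dialect."""


class DVHValidationError(SecmalError):
    """A DVH or derived record violates a structural invariant."""


class DegenerateOrganError(DVHValidationError):
    """An organ DVH carries zero total volume and cannot be normalized."""


class UnknownOrganError(SecmalError, KeyError):
    """Organ label outside the supported vocabulary."""


class PairingError(SecmalError):
    """Proton and photon plans of one patient do not match up."""


class UndefinedRatioError(SecmalError):
    """Relative risk is undefined because the photon OED is zero."""


class NoInformationError(SecmalError):
    """All paired differences are zero; the signed-rank test carries no information."""


class InsufficientDataError(SecmalError):
    """Fewer informative pairs than the minimum required for a paired test."""


class DomainError(SecmalError, ValueError):
    """A numeric argument is outside the physically meaningful domain."""
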