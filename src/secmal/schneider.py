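"""Organ equivalent dose (OED) and proton/photon relative risk.

The OED framework declares two dose distributions in an organ equivalent if
they induce the same cancer incidence. The per-bin risk-equivalent dose
RED(D) is averaged over the differential DVH:

    OED = sum_i v_i * RED(D_i) / sum_i v_i

under three dose-response scenarios:

    linear              RED = D
    linear-exponential  RED = D * exp(-a' * D)      (no repopulation/repair)
    plateau             RED = (1 - exp(-a' * D))/a' (complete repopulation)

where the cell-kill slope is fractionation-corrected per bin via the LQ
model, a' = a + (a / (a/b)) * D/n, with ``a`` the organ's cell-kill
coefficient (the Dasu a2 of the shared coefficient table) and ``n`` the
number of fractions. The relative risk of one organ is the ratio of proton
to photon OED under the same scenario; values below 1 favour protons.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .dasu import RiskCoefficients, beta_of
from .dvh_io import DifferentialDVH
from .errors import DomainError, DVHValidationError, UndefinedRatioError


class REDModel(str, Enum):
    """Dose-response scenario for the risk-equivalent dose."""

    LINEAR = "linear"
    LINEAR_EXPONENTIAL = "linear_exponential"
    PLATEAU = "plateau"


RED_VARIANTS = tuple(REDModel)


@dataclass(frozen=True)
class OEDResult:
    organ: str
    variant: REDModel
    oed: float  # Gy(RBE)

    def __post_init__(self) -> None:
        if self.oed < 0:
            raise DomainError(f"{self.organ}: OED must be >= 0")


@dataclass(frozen=True)
class RelativeRisk:
    organ: str
    variant: REDModel
    rr: float  # dimensionless, proton OED / photon OED

    def __post_init__(self) -> None:
        if not np.isfinite(self.rr) or self.rr < 0:
            raise DomainError(f"{self.organ}: relative risk must be finite and >= 0")


def alpha_prime(alpha: float, alpha_beta_ratio: float, dose, n_fractions: int):
    """Fractionation-corrected cell-kill slope a + b*D/n (1/Gy)."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise DomainError("dose must be >= 0")
    if n_fractions < 1:
        raise DomainError("n_fractions must be >= 1")
    out = alpha + beta_of(alpha, alpha_beta_ratio) * dose / n_fractions
    return out if out.ndim else float(out)


def red(dose, variant: REDModel, a_prime=None):
    """Risk-equivalent dose of a bin under one dose-response scenario.

    ``a_prime`` is required for the nonlinear variants and may be per-bin
    (an array matching ``dose``). All variants satisfy 0 <= RED <= D.
    """
    variant = REDModel(variant)
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise DomainError("dose must be >= 0")
    if variant is REDModel.LINEAR:
        out = dose
    else:
        if a_prime is None or np.any(np.asarray(a_prime) <= 0):
            raise DomainError(f"{variant.value} RED needs a_prime > 0")
        a_prime = np.asarray(a_prime, dtype=float)
        if variant is REDModel.LINEAR_EXPONENTIAL:
            out = dose * np.exp(-a_prime * dose)
        else:  # plateau; expm1 keeps the D -> 0 limit accurate
            out = -np.expm1(-a_prime * dose) / a_prime
    return out if out.ndim else float(out)


def oed(
    dvh: DifferentialDVH,
    variant: REDModel,
    coeffs: RiskCoefficients,
    n_fractions: int,
) -> OEDResult:
    """Volume-weighted mean RED over a differential DVH.

    The cell-kill slope is re-evaluated per bin from the organ's ``alpha2``
    (the bin dose enters the fractionation correction).
    """
    variant = REDModel(variant)
    if dvh.doses.size == 0:
        raise DVHValidationError(f"{dvh.organ}: empty DVH")
    a_prime = alpha_prime(coeffs.alpha2, coeffs.alpha_beta_ratio, dvh.doses, n_fractions)
    reds = red(dvh.doses, variant, a_prime)
    weights = dvh.volume_fractions
    value = float(np.dot(weights, reds) / weights.sum())
    return OEDResult(dvh.organ, variant, value)


def relative_risk(oed_proton: OEDResult, oed_photon: OEDResult) -> RelativeRisk:
    """Proton-to-photon OED ratio for one organ and scenario."""
    if oed_proton.organ != oed_photon.organ or oed_proton.variant != oed_photon.variant:
        raise DomainError("relative risk requires matching organ and RED variant")
    if oed_photon.oed == 0:
        raise UndefinedRatioError(
            f"{oed_photon.organ} ({oed_photon.variant.value}): photon OED is zero"
        )
    return RelativeRisk(oed_proton.organ, oed_proton.variant, oed_proton.oed / oed_photon.oed)
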