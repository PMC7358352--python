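"""Dasu linear-quadratic competition model for secondary-cancer induction.

The per-bin risk contribution competes mutation induction against cell kill:

    risk(D) = (a1*D + b1*D^2/n) * exp(-(a2*D + b2*D^2/n))

with ``b = a / (a/b ratio)`` for both coefficient pairs and ``n`` the number
of fractions of the whole plan. The organ risk is the volume-weighted mean of
the per-bin contribution over a differential DVH. ``a1`` carries the
ICRP-style population-averaged induction risk per Gy and comes in two
flavours: *total* (any secondary cancer) and *fatal* (secondary cancer
leading to death); ``a2`` governs the cell-kill turnover.

Default coefficients (per Gy, one row shared by the left/right organs of a
bilateral pair):

    ===========  =========  =========  ======
    organ        a1 fatal   a1 total   a2
    ===========  =========  =========  ======
    lung         0.0101     0.0144     0.129
    breast       0.0028     0.0144     0.008
    esophagus    0.0014     0.0015     0.274
    ===========  =========  =========  ======

with a common alpha/beta ratio of 3 Gy. Alternative coefficients can be
supplied through a YAML file for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import yaml

from .dvh_io import ORGANS, DifferentialDVH
from .errors import DomainError, DVHValidationError, UnknownOrganError

RISK_KINDS = ("total", "fatal")

DEFAULT_ALPHA_BETA = 3.0  # Gy, shared by lungs, breasts and esophagus

#: Organ label -> shared coefficient row (both lungs use "lung", etc.).
ORGAN_COEFFICIENT_GROUP = {
    "lung_right": "lung",
    "lung_left": "lung",
    "breast_right": "breast",
    "breast_left": "breast",
    "esophagus": "esophagus",
}

#: (alpha1_fatal, alpha1_total, alpha2), all in 1/Gy.
_COEFFICIENT_TABLE = {
    "lung": (0.0101, 0.0144, 0.129),
    "breast": (0.0028, 0.0144, 0.008),
    "esophagus": (0.0014, 0.0015, 0.274),
}


@dataclass(frozen=True)
class RiskCoefficients:
    """Per-organ risk coefficients of the LQ competition model."""

    organ: str
    alpha1_fatal: float  # 1/Gy
    alpha1_total: float  # 1/Gy
    alpha2: float  # 1/Gy
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA  # Gy

    def __post_init__(self) -> None:
        for name in ("alpha1_fatal", "alpha1_total", "alpha2", "alpha_beta_ratio"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{self.organ}: {name} must be > 0")
        if self.alpha1_fatal > self.alpha1_total:
            raise DomainError(
                f"{self.organ}: fatal-risk coefficient exceeds total-risk coefficient"
            )

    def alpha1(self, kind: str) -> float:
        if kind not in RISK_KINDS:
            raise ValueError(f"risk kind must be one of {RISK_KINDS}, got {kind!r}")
        return self.alpha1_fatal if kind == "fatal" else self.alpha1_total


@dataclass(frozen=True)
class DasuRisk:
    """Volume-averaged induction risk of one organ, as a fraction in [0, 1]."""

    organ: str
    risk_kind: str
    risk: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk <= 1.0:
            raise DomainError(f"{self.organ}: risk {self.risk} outside [0, 1]")


def default_coefficients(organ: str) -> RiskCoefficients:
    """Return the built-in coefficients for one of the five supported organs."""
    try:
        group = ORGAN_COEFFICIENT_GROUP[organ]
    except KeyError:
        raise UnknownOrganError(organ) from None
    fatal, total, a2 = _COEFFICIENT_TABLE[group]
    return RiskCoefficients(organ, fatal, total, a2)


def load_coefficients(path=None) -> dict[str, RiskCoefficients]:
    """Coefficient set for all organs, optionally overridden from a YAML file.

    The YAML maps organ label -> {alpha1_fatal, alpha1_total, alpha2,
    alpha_beta_ratio}; absent organs and absent keys keep their defaults.
    """
    coeffs = {organ: default_coefficients(organ) for organ in ORGANS}
    if path is None:
        return coeffs
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    for organ, values in overrides.items():
        if organ not in coeffs:
            raise UnknownOrganError(organ)
        unknown = set(values) - {"alpha1_fatal", "alpha1_total", "alpha2", "alpha_beta_ratio"}
        if unknown:
            raise DomainError(f"{organ}: unknown coefficient keys {sorted(unknown)}")
        coeffs[organ] = replace(coeffs[organ], **{k: float(v) for k, v in values.items()})
    return coeffs


def beta_of(alpha: float, alpha_beta_ratio: float) -> float:
    """Quadratic LQ coefficient (1/Gy^2) from alpha and the alpha/beta ratio."""
    if alpha <= 0 or alpha_beta_ratio <= 0:
        raise DomainError("alpha and alpha/beta ratio must both be > 0")
    return alpha / alpha_beta_ratio


def dasu_bin_term(dose, n_fractions: int, coeffs: RiskCoefficients, kind: str):
    """Risk contribution of a single dose bin (scalar or array ``dose``)."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise DomainError("dose must be >= 0")
    if n_fractions < 1:
        raise DomainError("n_fractions must be >= 1")
    a1 = coeffs.alpha1(kind)
    a2 = coeffs.alpha2
    b1 = beta_of(a1, coeffs.alpha_beta_ratio)
    b2 = beta_of(a2, coeffs.alpha_beta_ratio)
    quad = dose * dose / n_fractions
    term = (a1 * dose + b1 * quad) * np.exp(-(a2 * dose + b2 * quad))
    return term if term.ndim else float(term)


def dasu_organ_risk(
    dvh: DifferentialDVH, n_fractions: int, coeffs: RiskCoefficients, kind: str
) -> DasuRisk:
    """Volume-weighted mean of the per-bin risk term over a differential DVH."""
    if dvh.doses.size == 0:
        raise DVHValidationError(f"{dvh.organ}: empty DVH")
    terms = dasu_bin_term(dvh.doses, n_fractions, coeffs, kind)
    weights = dvh.volume_fractions
    risk = float(np.dot(weights, terms) / weights.sum())
    return DasuRisk(dvh.organ, kind, risk)
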